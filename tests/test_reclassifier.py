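import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from euireclass.mlogit_core import fit_frame
from euireclass.records_io import EncodingMap, KNOWN_CAUSES, CauseClass
from euireclass.reclassifier import (
    AdjustmentResult,
    ClassMatrix,
    DEFAULT_ECP0_GRID,
    UNCLASSIFIED,
    agreement_share,
    assign_cause,
    assign_causes,
    build_class_matrix,
    build_misclass_matrix,
    fuzzy_sharing_redistribution,
    multinomial_pmf,
    population_adjust,
    proportional_redistribution,
    reclassify_euis,
    relative_error,
)
from euireclass.synthetic_data import (
    default_russia_like_config,
    generate,
    hidden_homicide_masking,
    uniform_masking,
)

CAUSE_NAMES = tuple(c.name for c in KNOWN_CAUSES)


def _random_probs(rng, n):
    p = rng.dirichlet(np.ones(3), size=n)
    return p


class TestAssignCause:
    def test_clear_max_above_threshold(self):
        assert assign_cause([0.8, 0.1, 0.1], 0.75) is CauseClass.NTA

    def test_below_threshold_unclassified(self):
        assert assign_cause([0.5, 0.3, 0.2], 0.75) is None

    def test_no_constraint_accepts_any_max(self):
        assert assign_cause([0.34, 0.33, 0.33], 0.0) is CauseClass.NTA

    def test_tie_breaks_to_lowest_index_and_is_counted(self):
        probs = np.array([[0.4, 0.4, 0.2], [0.3, 0.35, 0.35]])
        assigned, n_ties = assign_causes(probs, 0.0)
        assert assigned[0] == 0   # NTA before SUI
        assert assigned[1] == 1   # SUI before HOM
        assert n_ties == 2

    def test_threshold_uses_geq(self):
        assigned, _ = assign_causes(np.array([[0.75, 0.15, 0.10]]), 0.75)
        assert assigned[0] == 0

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            assign_cause([0.5, 0.3, 0.2], 1.5)


class TestClassMatrix:
    def test_perfect_classifier_diagonal(self):
        probs = np.zeros((300, 3))
        actual = np.repeat([0, 1, 2], 100)
        probs[np.arange(300), actual] = 1.0
        cm = build_class_matrix(probs, actual, 0.0)
        np.testing.assert_array_equal(cm.counts, np.eye(3) * 100)
        np.testing.assert_array_equal(cm.predicted_marginals, [100, 100, 100])
        assert cm.n_unclassified == 0

    def test_threshold_one_all_unclassified(self):
        rng = np.random.default_rng(0)
        probs = _random_probs(rng, 200)
        cm = build_class_matrix(probs, rng.integers(0, 3, 200), 1.0)
        assert cm.n_unclassified == 200
        assert cm.counts.sum() == 0

    @pytest.mark.parametrize("ecp0", [0.0, 0.5, 0.75, 0.9])
    def test_matches_naive_oracle(self, ecp0):
        """Exact agreement with per-record counting."""
        rng = np.random.default_rng(int(ecp0 * 100))
        probs = _random_probs(rng, 1000)
        actual = rng.integers(0, 3, 1000)
        cm = build_class_matrix(probs, actual, ecp0)
        expected = np.zeros((3, 3), dtype=int)
        unclassified = 0
        for p, a in zip(probs, actual):
            best = max(range(3), key=lambda i: (p[i], -i))
            if p[best] >= ecp0:
                expected[best, a] += 1
            else:
                unclassified += 1
        np.testing.assert_array_equal(cm.counts, expected)
        assert cm.n_unclassified == unclassified

    def test_marginal_identities(self):
        rng = np.random.default_rng(1)
        probs = _random_probs(rng, 500)
        actual = rng.integers(0, 3, 500)
        cm = build_class_matrix(probs, actual, 0.5)
        assert cm.counts.sum() + cm.n_unclassified == 500
        np.testing.assert_array_equal(cm.predicted_marginals, cm.counts.sum(axis=1))
        np.testing.assert_array_equal(cm.actual_marginals, cm.counts.sum(axis=0))

    def test_nested_classification_in_threshold(self):
        """Raising the threshold only removes records: d_ij entrywise monotone."""
        rng = np.random.default_rng(2)
        probs = _random_probs(rng, 800)
        actual = rng.integers(0, 3, 800)
        prev = None
        for ecp0 in DEFAULT_ECP0_GRID:
            cm = build_class_matrix(probs, actual, ecp0)
            if prev is not None:
                assert (cm.counts <= prev.counts).all()
                assert cm.n_unclassified >= prev.n_unclassified
            prev = cm


class TestErrorSummaries:
    def test_relative_error_diagonal_zero(self):
        cm = ClassMatrix(counts=np.eye(3, dtype=int) * 50, ecp0=0.0)
        np.testing.assert_array_equal(relative_error(cm), [0.0, 0.0, 0.0])

    def test_relative_error_arithmetic(self):
        counts = np.array([[80, 5, 5], [15, 90, 5], [5, 5, 90]])
        cm = ClassMatrix(counts=counts, ecp0=0.0)
        dp, da = counts.sum(axis=1), counts.sum(axis=0)
        np.testing.assert_allclose(relative_error(cm), (dp - da) / da)

    def test_relative_error_sums_to_zero_weighted(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(1, 100, (3, 3))
        cm = ClassMatrix(counts=counts, ecp0=0.0)
        da = cm.actual_marginals
        assert abs((da * relative_error(cm)).sum()) < 1e-9

    def test_relative_error_zero_actual_marginal(self):
        cm = ClassMatrix(counts=np.array([[5, 0, 1], [2, 0, 1], [1, 0, 3]]),
                         ecp0=0.0)
        with pytest.raises(ZeroDivisionError):
            relative_error(cm)

    def test_agreement_diagonal(self):
        cm = ClassMatrix(counts=np.eye(3, dtype=int) * 10, ecp0=0.0)
        share = agreement_share(cm)
        assert share.overall == 1.0
        np.testing.assert_array_equal(share.per_actual, [1.0, 1.0, 1.0])

    def test_agreement_arithmetic(self):
        counts = np.array([[90, 5, 5], [10, 80, 10], [20, 10, 70]])
        share = agreement_share(ClassMatrix(counts=counts, ecp0=0.0))
        assert share.overall == pytest.approx(240 / 300)
        np.testing.assert_allclose(share.per_actual, [90 / 120, 80 / 95, 70 / 85])

    def test_agreement_empty_matrix_errors(self):
        with pytest.raises(ValueError):
            agreement_share(ClassMatrix(counts=np.zeros((3, 3), int), ecp0=1.0))


class TestMisclassMatrix:
    def test_diagonal_gives_identity(self):
        cm = ClassMatrix(counts=np.eye(3, dtype=int) * 7, ecp0=0.0)
        mm = build_misclass_matrix(cm)
        np.testing.assert_array_equal(mm.p, np.eye(3))
        assert mm.defined.all()

    def test_row_normalization_arithmetic(self):
        counts = np.array([[90, 5, 5], [10, 80, 10], [20, 10, 70]])
        mm = build_misclass_matrix(ClassMatrix(counts=counts, ecp0=0.0))
        np.testing.assert_allclose(mm.p[0], [0.9, 0.05, 0.05])
        np.testing.assert_allclose(mm.p.sum(axis=1), [1, 1, 1])

    def test_reconstruction_identity_fuzz(self):
        """sum_i P_ij D_i^P == D_j^A exactly."""
        rng = np.random.default_rng(4)
        for _ in range(20):
            counts = rng.integers(0, 50, (3, 3))
            counts += np.eye(3, dtype=counts.dtype)  # keep rows nonzero
            cm = ClassMatrix(counts=counts, ecp0=0.0)
            mm = build_misclass_matrix(cm)
            np.testing.assert_allclose(
                mm.p.T @ cm.predicted_marginals, cm.actual_marginals, atol=1e-9
            )

    def test_zero_row_flagged(self):
        counts = np.array([[0, 0, 0], [10, 80, 10], [20, 10, 70]])
        mm = build_misclass_matrix(ClassMatrix(counts=counts, ecp0=0.0))
        assert not mm.defined[0]
        assert mm.defined[1] and mm.defined[2]


class TestReclassifyEuis:
    def test_no_threshold_all_classified(self):
        rng = np.random.default_rng(5)
        adj = reclassify_euis(_random_probs(rng, 400), 0.0)
        assert adj.n_unclassified == 0
        assert adj.u.sum() == 400

    def test_unclassified_monotone_in_threshold(self):
        rng = np.random.default_rng(6)
        probs = _random_probs(rng, 600)
        counts = [reclassify_euis(probs, e).n_unclassified
                  for e in DEFAULT_ECP0_GRID]
        assert counts == sorted(counts)

    def test_mass_conservation(self):
        rng = np.random.default_rng(7)
        probs = _random_probs(rng, 300)
        for ecp0 in DEFAULT_ECP0_GRID:
            adj = reclassify_euis(probs, ecp0)
            assert adj.u.sum() + adj.n_unclassified == 300


class TestPopulationAdjust:
    def test_identity_p(self):
        mm = build_misclass_matrix(
            ClassMatrix(counts=np.eye(3, dtype=int) * 5, ecp0=0.0)
        )
        np.testing.assert_allclose(
            population_adjust(mm, np.array([10, 20, 30])), [10, 20, 30]
        )

    def test_hand_arithmetic(self):
        p = np.array([[0.9, 0.05, 0.05], [0.1, 0.8, 0.1], [0.2, 0.1, 0.7]])
        from euireclass.reclassifier import MisclassMatrix

        mm = MisclassMatrix(p=p, defined=np.ones(3, bool))
        u_adj = population_adjust(mm, np.array([100, 50, 50]))
        np.testing.assert_allclose(u_adj, [105, 50, 45])

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=50, deadline=None)
    def test_conserves_total(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.dirichlet(np.ones(3), size=3)
        from euireclass.reclassifier import MisclassMatrix

        mm = MisclassMatrix(p=p, defined=np.ones(3, bool))
        u = rng.integers(0, 1000, 3).astype(float)
        assert population_adjust(mm, u).sum() == pytest.approx(u.sum())

    def test_undefined_row_with_mass_errors(self):
        counts = np.array([[0, 0, 0], [10, 80, 10], [20, 10, 70]])
        mm = build_misclass_matrix(ClassMatrix(counts=counts, ecp0=0.0))
        with pytest.raises(ValueError):
            population_adjust(mm, np.array([5, 1, 1]))


class TestComparators:
    def test_proportional_stratum_split(self):
        known = pd.DataFrame(
            {"NTA": [60], "SUI": [30], "HOM": [10]}, index=["s1"]
        )
        eui = pd.Series({"s1": 10.0})
        out = proportional_redistribution(known, eui)
        np.testing.assert_allclose(out.loc["s1"], [6, 3, 1])

    def test_totals_conserved_per_stratum(self):
        rng = np.random.default_rng(8)
        known = pd.DataFrame(
            rng.integers(1, 50, (5, 3)), columns=list(CAUSE_NAMES),
            index=[f"s{i}" for i in range(5)],
        )
        eui = pd.Series(rng.integers(0, 30, 5).astype(float), index=known.index)
        out = proportional_redistribution(known, eui)
        np.testing.assert_allclose(out.sum(axis=1), eui)

    def test_zero_stratum_falls_back_to_sex_margin(self):
        idx = pd.MultiIndex.from_tuples(
            [("male", "0-14"), ("male", "65+")], names=["sex", "age_group"]
        )
        known = pd.DataFrame(
            [[0, 0, 0], [80, 10, 10]], columns=list(CAUSE_NAMES), index=idx
        )
        eui = pd.Series([10.0, 0.0], index=idx)
        out = proportional_redistribution(known, eui)
        np.testing.assert_allclose(out.loc[("male", "0-14")], [8, 1, 1])

    def test_all_zero_errors(self):
        known = pd.DataFrame({"NTA": [0], "SUI": [0], "HOM": [0]}, index=["s"])
        with pytest.raises(ValueError):
            proportional_redistribution(known, pd.Series({"s": 5.0}))

    def test_fuzzy_degenerate(self):
        probs = np.tile([1.0, 0.0, 0.0], (7, 1))
        np.testing.assert_allclose(
            fuzzy_sharing_redistribution(probs), [7, 0, 0]
        )

    def test_fuzzy_single_record(self):
        np.testing.assert_allclose(
            fuzzy_sharing_redistribution(np.array([[0.8, 0.1, 0.1]])),
            [0.8, 0.1, 0.1],
        )

    def test_fuzzy_conserves_total(self):
        rng = np.random.default_rng(9)
        probs = _random_probs(rng, 123)
        assert fuzzy_sharing_redistribution(probs).sum() == pytest.approx(123)


class TestMultinomialPmf:
    def test_paper_example(self):
        assert round(multinomial_pmf((8, 1, 1), (0.8, 0.1, 0.1)), 3) == 0.151

    def test_degenerate(self):
        assert multinomial_pmf((10, 0, 0), (1.0, 0.0, 0.0)) == pytest.approx(1.0)

    def test_sums_to_one_over_compositions(self):
        """Brute-force enumeration of all compositions of n=5."""
        p = (0.5, 0.3, 0.2)
        total = 0.0
        for a in range(6):
            for b in range(6 - a):
                c = 5 - a - b
                total += multinomial_pmf((a, b, c), p)
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_matches_scipy(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            p = rng.dirichlet(np.ones(3))
            c = rng.integers(0, 8, 3)
            assert multinomial_pmf(tuple(c), tuple(p)) == pytest.approx(
                stats.multinomial.pmf(c, int(c.sum()), p), abs=1e-12
            )

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            multinomial_pmf((1, 2), (0.5, 0.3, 0.2))


class TestRecoveryScenarios:
    def test_uniform_masking_recovery(self):
        """U_i distribution tracks the true cause mix of masked records."""
        config = default_russia_like_config(
            n_records=50_000, seed=21, masking=uniform_masking(0.15)
        )
        frame, truth = generate(config)
        known = frame[frame["cause_class"].isin(CAUSE_NAMES)]
        encoding = EncodingMap.from_schema(config.schema, training=known)
        merged = frame.merge(truth, on="record_id")
        u_adj_total = np.zeros(3)
        true_masked_total = np.zeros(3)
        for sex in ("male", "female"):
            train = known[known["sex"] == sex]
            model = fit_frame(train, encoding)
            Xk = encoding.encode_frame(train)
            actual = train["cause_class"].map(
                {c.name: c.index for c in KNOWN_CAUSES}
            ).to_numpy()
            cm = build_class_matrix(model.predict_proba(Xk), actual, 0.0)
            mm = build_misclass_matrix(cm)
            euis = frame[(frame["cause_class"] == "EUI") & (frame["sex"] == sex)]
            pe = model.predict_proba(encoding.encode_frame(euis))
            adj = reclassify_euis(pe, 0.0)
            u_adj_total += population_adjust(mm, adj.u)
            masked = merged[
                (merged["cause_class"] == "EUI") & (merged["sex"] == sex)
            ]["true_cause"].value_counts()
            true_masked_total += np.array(
                [masked.get(c, 0) for c in CAUSE_NAMES], dtype=float
            )
        shares_est = u_adj_total / u_adj_total.sum()
        shares_true = true_masked_total / true_masked_total.sum()
        np.testing.assert_allclose(shares_est, shares_true, atol=0.02)

    def test_hidden_homicide_model_beats_proportional(self):
        """Under elevated homicide masking the model assigns a strictly larger
        homicide share to EUIs than sex/age-proportional redistribution."""
        config = default_russia_like_config(
            n_records=30_000, seed=22, masking=hidden_homicide_masking(0.05, 0.45)
        )
        frame, _ = generate(config)
        known = frame[frame["cause_class"].isin(CAUSE_NAMES)]
        encoding = EncodingMap.from_schema(config.schema, training=known)
        train = known[known["sex"] == "male"]
        model = fit_frame(train, encoding)
        euis = frame[(frame["cause_class"] == "EUI") & (frame["sex"] == "male")]
        pe = model.predict_proba(encoding.encode_frame(euis))
        adj = reclassify_euis(pe, 0.0)
        model_hom_share = adj.u[2] / adj.u.sum()

        strata_known = (
            train.groupby(["sex", "age_group"])["cause_class"]
            .value_counts().unstack(fill_value=0)
            .reindex(columns=list(CAUSE_NAMES), fill_value=0)
        )
        strata_eui = (
            euis.groupby(["sex", "age_group"]).size()
            .reindex(strata_known.index, fill_value=0)
        )
        prop = proportional_redistribution(strata_known, strata_eui)
        prop_hom_share = prop["HOM"].sum() / prop.to_numpy().sum()
        assert model_hom_share > prop_hom_share
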