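"""Threshold-based cause assignment, predicted-by-actual matrices, the
misclassification matrix, population-level adjustment of undetermined-intent
deaths, and comparator redistributions.

All 3x3 matrices index predicted cause by row (i) and actual cause by
column (j) in the fixed order NTA, SUI, HOM.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .mlogit_core import ECPVector, MlogitModel
from .records_io import KNOWN_CAUSES, CauseClass

__all__ = [
    "UNCLASSIFIED",
    "DEFAULT_ECP0_GRID",
    "ClassMatrix",
    "MisclassMatrix",
    "AdjustmentResult",
    "assign_cause",
    "assign_causes",
    "build_class_matrix",
    "relative_error",
    "agreement_share",
    "build_misclass_matrix",
    "reclassify_euis",
    "population_adjust",
    "proportional_redistribution",
    "fuzzy_sharing_redistribution",
    "multinomial_pmf",
]

#: Integer code for records whose maximal ECP falls below the threshold.
UNCLASSIFIED = -1

#: The evaluation grid: the unconstrained case plus thresholds 0.5-0.9.
DEFAULT_ECP0_GRID = (0.0, 0.5, 0.6, 0.7, 0.75, 0.8, 0.85, 0.9)


def _check_ecp0(ecp0: float) -> float:
    ecp0 = float(ecp0)
    if not (0.0 <= ecp0 <= 1.0):
        raise ValueError(f"ECP threshold must lie in [0, 1], got {ecp0}")
    return ecp0


def assign_causes(probs: np.ndarray, ecp0: float):
    """Vectorized threshold assignment.

    Returns ``(assigned, n_ties)`` where ``assigned[n]`` is the 0-based cause
    index of the maximal ECP when it reaches ``ecp0`` and ``UNCLASSIFIED``
    otherwise.  Exact ties on the maximum resolve to the lowest cause index
    (NTA < SUI < HOM) and are counted.
    """
    ecp0 = _check_ecp0(ecp0)
    P = np.atleast_2d(np.asarray(probs, dtype=float))
    best = P.max(axis=1)
    assigned = P.argmax(axis=1)  # argmax takes the first max: fixed-order ties
    n_ties = int(((P == best[:, None]).sum(axis=1) > 1).sum())
    assigned = np.where(best >= ecp0, assigned, UNCLASSIFIED)
    return assigned.astype(np.int64), n_ties


def assign_cause(
    ecp: Union[ECPVector, Sequence[float]], ecp0: float
) -> Optional[CauseClass]:
    """Single-record threshold assignment; ``None`` means unclassified."""
    probs = ecp.probs if isinstance(ecp, ECPVector) else np.asarray(ecp, float)
    assigned, _ = assign_causes(probs[None, :], ecp0)
    if assigned[0] == UNCLASSIFIED:
        return None
    return KNOWN_CAUSES[assigned[0]]


@dataclasses.dataclass
class ClassMatrix:
    """Counts ``d_ij`` of predicted (row i) by actual (column j) causes at a
    given threshold, plus the count left unclassified."""

    counts: np.ndarray
    ecp0: float
    n_unclassified: int = 0
    n_ties: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (3, 3):
            raise ValueError("class matrix must be 3x3")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def predicted_marginals(self) -> np.ndarray:
        """D_i^P = sum_j d_ij."""
        return self.counts.sum(axis=1)

    @property
    def actual_marginals(self) -> np.ndarray:
        """D_j^A = sum_i d_ij."""
        return self.counts.sum(axis=0)

    @property
    def n_classified(self) -> int:
        return int(self.counts.sum())

    @property
    def n_scored(self) -> int:
        return self.n_classified + self.n_unclassified

    def per_1000(self) -> np.ndarray:
        """Relative distribution scaled to 1000 classified deaths."""
        total = self.counts.sum()
        if total == 0:
            return np.zeros((3, 3))
        return 1000.0 * self.counts / total


def build_class_matrix(
    probs: np.ndarray, actual: np.ndarray, ecp0: float
) -> ClassMatrix:
    """Cross-classify scored known-cause records at threshold ``ecp0``.

    ``probs`` is (n, 3); ``actual`` holds 0-based true cause indices.
    """
    actual = np.asarray(actual, dtype=int)
    assigned, n_ties = assign_causes(probs, ecp0)
    keep = assigned != UNCLASSIFIED
    counts = np.zeros((3, 3), dtype=np.int64)
    np.add.at(counts, (assigned[keep], actual[keep]), 1)
    return ClassMatrix(
        counts=counts,
        ecp0=float(ecp0),
        n_unclassified=int((~keep).sum()),
        n_ties=n_ties,
    )


def relative_error(matrix: ClassMatrix) -> np.ndarray:
    """Signed proportions ``(D_i^P - D_i^A) / D_i^A`` per cause."""
    dp = matrix.predicted_marginals.astype(float)
    da = matrix.actual_marginals.astype(float)
    if (da == 0).any():
        raise ZeroDivisionError(
            "relative error undefined: zero actual marginal for cause(s) "
            f"{[KNOWN_CAUSES[i].name for i in np.where(da == 0)[0]]}"
        )
    return (dp - da) / da


@dataclasses.dataclass
class AgreementShare:
    overall: float
    per_actual: np.ndarray


def agreement_share(matrix: ClassMatrix) -> AgreementShare:
    """Overall and per-actual-cause shares of correct predictions."""
    d = matrix.counts.astype(float)
    total = d.sum()
    if total == 0:
        raise ValueError("empty class matrix")
    da = matrix.actual_marginals.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        per = np.where(da > 0, np.diag(d) / da, np.nan)
    return AgreementShare(overall=float(np.trace(d) / total), per_actual=per)


@dataclasses.dataclass
class MisclassMatrix:
    """Row-normalized class matrix: ``P_ij = d_ij / D_i^P`` estimates the
    probability that a death predicted as cause i is actually cause j.
    Rows with no predicted deaths are flagged, never silently zeroed."""

    p: np.ndarray
    defined: np.ndarray

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        self.defined = np.asarray(self.defined, dtype=bool)
        if self.p.shape != (3, 3) or self.defined.shape != (3,):
            raise ValueError("misclassification matrix must be 3x3")
        for i in range(3):
            if self.defined[i]:
                row = self.p[i]
                if (row < -1e-12).any() or (row > 1 + 1e-12).any():
                    raise ValueError("P entries outside [0, 1]")
                if abs(row.sum() - 1.0) > 1e-9:
                    raise ValueError("defined P rows must sum to 1")


def build_misclass_matrix(matrix: ClassMatrix) -> MisclassMatrix:
    d = matrix.counts.astype(float)
    dp = matrix.predicted_marginals.astype(float)
    defined = dp > 0
    p = np.zeros((3, 3))
    for i in range(3):
        if defined[i]:
            p[i] = d[i] / dp[i]
    return MisclassMatrix(p=p, defined=defined)


@dataclasses.dataclass
class AdjustmentResult:
    """EUI counts assigned per cause at one threshold, optionally with the
    population-level adjusted totals."""

    u: np.ndarray                     # counts assigned to NTA, SUI, HOM
    n_unclassified: int
    ecp0: float
    u_adjusted: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u)
        if self.u.shape != (3,):
            raise ValueError("U must have three entries")

    @property
    def n_total(self) -> int:
        return int(self.u.sum()) + self.n_unclassified


def reclassify_euis(probs: np.ndarray, ecp0: float) -> AdjustmentResult:
    """Count EUI deaths assigned to each cause at threshold ``ecp0``."""
    assigned, _ = assign_causes(probs, ecp0)
    u = np.array([(assigned == i).sum() for i in range(3)], dtype=np.int64)
    return AdjustmentResult(
        u=u,
        n_unclassified=int((assigned == UNCLASSIFIED).sum()),
        ecp0=float(ecp0),
    )


def population_adjust(p: MisclassMatrix, u: np.ndarray) -> np.ndarray:
    """Population-level redistribution ``U_j^Adj = sum_i P_ij U_i``.

    Conserves the total mass of classified EUIs, mirroring the identity
    ``D_j^A = sum_i P_ij D_i^P`` on the training set.
    """
    u = np.asarray(u, dtype=float)
    if u.shape != (3,):
        raise ValueError("U must have three entries")
    if ((~p.defined) & (u > 0)).any():
        bad = [KNOWN_CAUSES[i].name for i in np.where(~p.defined & (u > 0))[0]]
        raise ValueError(
            f"misclassification rows undefined for predicted cause(s) {bad} "
            "with nonzero EUI counts"
        )
    return p.p.T @ u


def proportional_redistribution(
    known_counts: pd.DataFrame, eui_counts: pd.Series
) -> pd.DataFrame:
    """Default comparator: split each stratum's EUIs proportionally to its
    known-cause counts.

    ``known_counts`` has one row per stratum (e.g. sex x age group) and one
    column per cause; ``eui_counts`` is aligned on the same index.  Strata
    with no known deaths fall back to the margin over the stratum's ``sex``
    index level (overall margin if there is none).
    """
    causes = [c.name for c in KNOWN_CAUSES]
    known = known_counts.reindex(columns=causes).astype(float)
    eui = eui_counts.reindex(known.index).fillna(0.0).astype(float)
    if float(known.to_numpy().sum()) == 0.0:
        raise ValueError("no known-cause deaths to define proportions")

    out = pd.DataFrame(0.0, index=known.index, columns=causes)
    totals = known.sum(axis=1)
    has_sex = (
        isinstance(known.index, pd.MultiIndex) and "sex" in (known.index.names or [])
    ) or known.index.name == "sex"
    for stratum in known.index:
        row = known.loc[stratum]
        if totals.loc[stratum] > 0:
            shares = row / totals.loc[stratum]
        else:
            if has_sex:
                if isinstance(known.index, pd.MultiIndex):
                    sex = stratum[known.index.names.index("sex")]
                    margin = known.xs(sex, level="sex").sum(axis=0)
                else:
                    margin = known.loc[[stratum]].sum(axis=0)
            else:
                margin = known.sum(axis=0)
            if margin.sum() == 0:
                margin = known.sum(axis=0)
            shares = margin / margin.sum()
        out.loc[stratum] = shares.to_numpy() * eui.loc[stratum]
    return out


def fuzzy_sharing_redistribution(probs: np.ndarray) -> np.ndarray:
    """Proportional-sharing comparator: each EUI contributes its full ECP
    vector, so cause totals are column sums of the probabilities."""
    P = np.atleast_2d(np.asarray(probs, dtype=float))
    return P.sum(axis=0)


def multinomial_pmf(counts: Sequence[int], probs: Sequence[float]) -> float:
    """Multinomial probability mass, computed in log space."""
    c = np.asarray(counts)
    p = np.asarray(probs, dtype=float)
    if c.shape != p.shape:
        raise ValueError("counts and probabilities must have equal length")
    if (c < 0).any() or not np.issubdtype(c.dtype, np.integer):
        raise ValueError("counts must be nonnegative integers")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("probabilities must sum to 1")
    n = int(c.sum())
    with np.errstate(divide="ignore"):
        logs = np.where(c > 0, c * np.log(np.where(p > 0, p, 1.0)), 0.0)
    if ((c > 0) & (p == 0)).any():
        return 0.0
    log_pmf = gammaln(n + 1) - gammaln(c + 1).sum() + logs.sum()
    return float(np.exp(log_pmf))
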