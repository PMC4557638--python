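"""End-to-end orchestration used by the CLI.

Stages: ingest or generate microdata -> fit one model per sex on the
known-cause training set -> evaluate over the ECP threshold grid ->
reclassify EUI deaths -> population-level adjustment -> comparator
redistributions -> rate tables -> bootstrap stability -> manifest.
Every artifact is a plain CSV/JSON file so stages are independently
inspectable and reruns with the same config and seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .bootstrap import DEFAULT_N_REPLICATES, stability_analysis
from .mlogit_core import MlogitModel, fit_frame
from .rates import adjusted_series, european_standard
from .reclassifier import (
    DEFAULT_ECP0_GRID,
    agreement_share,
    assign_causes,
    build_class_matrix,
    build_misclass_matrix,
    fuzzy_sharing_redistribution,
    population_adjust,
    proportional_redistribution,
    reclassify_euis,
    relative_error,
    UNCLASSIFIED,
)
from .records_io import (
    KNOWN_CAUSES,
    SEXES,
    CauseClass,
    EncodingMap,
    Schema,
    read_microdata_frame,
)
from .synthetic_data import (
    GeneratorConfig,
    generate,
    population_frame,
)

logger = logging.getLogger(__name__)

CAUSE_NAMES = tuple(c.name for c in KNOWN_CAUSES)


@dataclasses.dataclass
class RunConfig:
    """Pipeline settings; either a generator config or an input CSV path."""

    generator: Optional[GeneratorConfig] = None
    input_path: Optional[str] = None
    population_path: Optional[str] = None
    ecp0_grid: Sequence[float] = DEFAULT_ECP0_GRID
    bootstrap_replicates: int = DEFAULT_N_REPLICATES
    bootstrap_records: Optional[int] = 20_000
    seed: int = 0
    per_sex: bool = True
    comparators: bool = True
    adjust_ecp0: float = 0.0

    def validate(self) -> None:
        grid = list(self.ecp0_grid)
        if any(not (0.0 <= g <= 1.0) for g in grid):
            raise ValueError("ECP grid values must lie in [0, 1]")
        if sorted(grid) != grid or len(set(grid)) != len(grid):
            raise ValueError("ECP grid must be strictly increasing")
        if self.bootstrap_replicates < 0:
            raise ValueError("bootstrap replicate count must be nonnegative")
        if (self.generator is None) == (self.input_path is None):
            raise ValueError("exactly one of generator/input_path must be set")


def _jsonable(obj):
    if isinstance(obj, CauseClass):
        return obj.name
    if isinstance(obj, Schema):
        return {f: list(v) for f, v in obj.levels.items()}
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _jsonable(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {str(_jsonable(k)): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (str, int, float, bool)) or obj is None:
        return obj
    return str(obj)


def _config_digest(config: RunConfig) -> str:
    blob = json.dumps(_jsonable(config), sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()


def run(config: RunConfig, outdir) -> Path:
    """Execute the whole pipeline; returns the artifact directory."""
    config.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: Dict = {
        "version": __version__,
        "seed": config.seed,
        "config_sha256": _config_digest(config),
        "ecp0_grid": list(config.ecp0_grid),
        "stages": {},
    }

    # --- ingest / generate -------------------------------------------------
    population = None
    if config.generator is not None:
        frame, truth = generate(config.generator)
        schema = config.generator.schema
        truth.to_csv(out / "truth.csv", index=False)
        frame.to_csv(out / "microdata.csv", index=False)
        if config.generator.population is not None:
            population = population_frame(config.generator)
        n_excluded = 0
    else:
        frame, n_excluded = read_microdata_frame(config.input_path)
        schema = Schema.from_frame(frame)
        if config.population_path:
            population = pd.read_csv(config.population_path, dtype={"year": str})
    manifest["stages"]["ingest"] = {
        "n_records": int(len(frame)),
        "n_excluded": int(n_excluded),
    }
    logger.info("ingested %d records (%d excluded)", len(frame), n_excluded)

    known = frame[frame["cause_class"].isin(CAUSE_NAMES)]
    euis = frame[frame["cause_class"] == "EUI"]
    manifest["stages"]["split"] = {"n_known": len(known), "n_eui": len(euis)}

    encoding = EncodingMap.from_schema(schema, training=known)
    sexes = list(SEXES) if config.per_sex else ["both"]

    models: Dict[str, MlogitModel] = {}
    eval_rows, matrix_rows, misclass_rows, eui_rows = [], [], [], []
    eui_assignment_frames = []
    bootstrap_summaries = {}
    standard = european_standard()
    rng = np.random.default_rng(config.seed)

    for sex in sexes:
        train = known if sex == "both" else known[known["sex"] == sex]
        model = fit_frame(train, encoding)
        model.save(out / f"model_{sex}.json")
        models[sex] = model
        X_train = encoding.encode_frame(train)
        probs_train = model.predict_proba(X_train)
        actual = train["cause_class"].map(
            {c.name: c.index for c in KNOWN_CAUSES}
        ).to_numpy()

        sex_eui = euis if sex == "both" else euis[euis["sex"] == sex]
        probs_eui = (
            model.predict_proba(encoding.encode_frame(sex_eui))
            if len(sex_eui)
            else np.zeros((0, 3))
        )

        for ecp0 in config.ecp0_grid:
            cm = build_class_matrix(probs_train, actual, ecp0)
            share = agreement_share(cm)
            rel = relative_error(cm)
            eval_rows.append(
                {
                    "sex": sex,
                    "ecp0": ecp0,
                    "n_classified": cm.n_classified,
                    "n_unclassified": cm.n_unclassified,
                    "overall_agreement": share.overall,
                    **{
                        f"agreement_{c}": share.per_actual[i]
                        for i, c in enumerate(CAUSE_NAMES)
                    },
                    **{
                        f"relative_error_{c}": rel[i]
                        for i, c in enumerate(CAUSE_NAMES)
                    },
                }
            )
            per1000 = cm.per_1000()
            for i, pred in enumerate(CAUSE_NAMES):
                for j, act in enumerate(CAUSE_NAMES):
                    matrix_rows.append(
                        {
                            "sex": sex,
                            "ecp0": ecp0,
                            "predicted": pred,
                            "actual": act,
                            "count": int(cm.counts[i, j]),
                            "per_1000": per1000[i, j],
                        }
                    )
            mm = build_misclass_matrix(cm)
            for i, pred in enumerate(CAUSE_NAMES):
                for j, act in enumerate(CAUSE_NAMES):
                    misclass_rows.append(
                        {
                            "sex": sex,
                            "ecp0": ecp0,
                            "predicted": pred,
                            "actual": act,
                            "p": mm.p[i, j] if mm.defined[i] else np.nan,
                        }
                    )

            if len(sex_eui):
                adj = reclassify_euis(probs_eui, ecp0)
                row = {
                    "sex": sex,
                    "ecp0": ecp0,
                    "variant": "threshold",
                    **{f"u_{c}": int(adj.u[i]) for i, c in enumerate(CAUSE_NAMES)},
                    "unclassified": adj.n_unclassified,
                }
                eui_rows.append(row)

        if len(sex_eui):
            # population-level adjustment at the configured threshold
            cm0 = build_class_matrix(probs_train, actual, config.adjust_ecp0)
            mm0 = build_misclass_matrix(cm0)
            adj0 = reclassify_euis(probs_eui, config.adjust_ecp0)
            u_adj = population_adjust(mm0, adj0.u)
            eui_rows.append(
                {
                    "sex": sex,
                    "ecp0": config.adjust_ecp0,
                    "variant": "population_adjusted",
                    **{f"u_{c}": u_adj[i] for i, c in enumerate(CAUSE_NAMES)},
                    "unclassified": adj0.n_unclassified,
                }
            )
            if config.comparators:
                strata_known = (
                    train.groupby(["sex", "age_group"])["cause_class"]
                    .value_counts()
                    .unstack(fill_value=0)
                    .reindex(columns=list(CAUSE_NAMES), fill_value=0)
                )
                strata_eui = (
                    sex_eui.groupby(["sex", "age_group"]).size()
                    .reindex(strata_known.index, fill_value=0)
                )
                prop = proportional_redistribution(strata_known, strata_eui)
                totals = prop.sum(axis=0)
                eui_rows.append(
                    {
                        "sex": sex,
                        "ecp0": np.nan,
                        "variant": "proportional",
                        **{f"u_{c}": totals[c] for c in CAUSE_NAMES},
                        "unclassified": 0,
                    }
                )
                fuzzy = fuzzy_sharing_redistribution(probs_eui)
                eui_rows.append(
                    {
                        "sex": sex,
                        "ecp0": np.nan,
                        "variant": "fuzzy_sharing",
                        **{f"u_{c}": fuzzy[i] for i, c in enumerate(CAUSE_NAMES)},
                        "unclassified": 0,
                    }
                )
            assigned, _ = assign_causes(probs_eui, config.adjust_ecp0)
            eui_assignment_frames.append(
                sex_eui.assign(
                    assigned_cause=[
                        CAUSE_NAMES[a] if a != UNCLASSIFIED else "unclassified"
                        for a in assigned
                    ]
                )
            )

        # bootstrap stability
        if config.bootstrap_replicates > 0:
            Xb = X_train
            if (
                config.bootstrap_records is not None
                and len(Xb) > config.bootstrap_records
            ):
                pick = rng.choice(len(Xb), config.bootstrap_records, replace=False)
                Xb = Xb[np.sort(pick)]
            report = stability_analysis(
                model, Xb, config.bootstrap_replicates, seed=config.seed
            )
            report.to_frame().to_csv(out / f"bootstrap_{sex}.csv", index=False)
            bootstrap_summaries[sex] = report.summary()

    pd.DataFrame(eval_rows).to_csv(out / "evaluation_summary.csv", index=False)
    pd.DataFrame(matrix_rows).to_csv(out / "class_matrices.csv", index=False)
    pd.DataFrame(misclass_rows).to_csv(out / "misclass_matrices.csv", index=False)
    if eui_rows:
        pd.DataFrame(eui_rows).to_csv(out / "eui_distribution.csv", index=False)
    else:
        logger.info("no EUI records present; skipping reclassification/adjustment")
        manifest["stages"]["reclassify"] = {"skipped": "no EUI records"}
    if bootstrap_summaries:
        with open(out / "bootstrap_summary.json", "w", encoding="utf-8") as fh:
            json.dump(bootstrap_summaries, fh, indent=1)

    # --- rate tables -------------------------------------------------------
    if population is not None:
        official = (
            known.groupby(["sex", "year", "cause_class", "age_group"])
            .size()
            .rename("deaths")
            .reset_index()
            .rename(columns={"cause_class": "cause"})
        )
        if eui_assignment_frames:
            eui_assigned = pd.concat(eui_assignment_frames)
            eui_assigned = eui_assigned[eui_assigned["assigned_cause"] != "unclassified"]
            contribution = (
                eui_assigned.groupby(["sex", "year", "assigned_cause", "age_group"])
                .size()
                .rename("deaths")
                .reset_index()
                .rename(columns={"assigned_cause": "cause"})
            )
        else:
            contribution = official.iloc[0:0]
        rate_table = adjusted_series(official, contribution, population, standard)
        rate_table.to_csv(out / "rates.csv", index=False)
        manifest["stages"]["rates"] = {"rows": len(rate_table)}

    manifest["stages"]["models"] = {
        sex: {"n_iter": m.n_iter, "loglike": m.loglike} for sex, m in models.items()
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1)
    return out
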