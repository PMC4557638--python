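"""Synthetic death-record microdata with known ground truth.

Records are drawn with a latent true cause (NTA/SUI/HOM), cause-conditional
covariate distributions, and a configurable masking mechanism that relabels
some deaths as "event of undetermined intent" (EUI).  Because the truth is
known, every downstream stage — classification, threshold reclassification,
population-level adjustment — can be checked quantitatively.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .records_io import (
    COVARIATE_FIELDS,
    KNOWN_AGE_GROUPS,
    KNOWN_CAUSES,
    SEXES,
    CauseClass,
    Schema,
    default_schema,
)

__all__ = [
    "MaskingRule",
    "GeneratorConfig",
    "ConfigError",
    "generate",
    "default_russia_like_config",
    "uniform_masking",
    "hidden_homicide_masking",
    "covariate_modulated_masking",
    "population_frame",
]

_PTOL = 1e-9


class ConfigError(ValueError):
    pass


def _check_dist(name: str, dist: Mapping[str, float]) -> None:
    probs = np.asarray(list(dist.values()), dtype=float)
    if (probs < -_PTOL).any():
        raise ConfigError(f"{name}: negative probability")
    if abs(probs.sum() - 1.0) > _PTOL:
        raise ConfigError(f"{name}: probabilities sum to {probs.sum()}, not 1")


@dataclasses.dataclass
class MaskingRule:
    """Per-cause probability of relabelling a death as EUI.

    ``modulators[field][level]`` multiplies the base probability for records
    taking that level (product over fields, clipped to [0, 1]).  Three named
    scenarios are provided by the module-level constructors.
    """

    base: Dict[CauseClass, float]
    modulators: Dict[str, Dict[str, float]] = dataclasses.field(default_factory=dict)
    scenario: str = "custom"

    def validate(self) -> None:
        for cause in KNOWN_CAUSES:
            p = self.base.get(cause)
            if p is None or not (0.0 <= p <= 1.0):
                raise ConfigError(f"masking probability for {cause.name} not in [0,1]")
        for field, mods in self.modulators.items():
            if field not in COVARIATE_FIELDS:
                raise ConfigError(f"masking modulator on unknown field {field!r}")
            for level, mult in mods.items():
                if mult < 0:
                    raise ConfigError(f"negative modulator for {field}={level}")

    def probabilities(self, true_cause_idx: np.ndarray, frame: pd.DataFrame) -> np.ndarray:
        base = np.array([self.base[c] for c in KNOWN_CAUSES], dtype=float)
        p = base[true_cause_idx]
        for field, mods in self.modulators.items():
            mult = frame[field].map(lambda lv: mods.get(str(lv), 1.0)).to_numpy(float)
            p = p * mult
        return np.clip(p, 0.0, 1.0)


def uniform_masking(p=0.15) -> MaskingRule:
    """Same masking probability for every cause (scalar or per-cause mapping)."""
    if isinstance(p, Mapping):
        base = {c: float(p[c]) for c in KNOWN_CAUSES}
    else:
        base = {c: float(p) for c in KNOWN_CAUSES}
    return MaskingRule(base=base, scenario="uniform")


def hidden_homicide_masking(base: float = 0.10, hom: float = 0.40) -> MaskingRule:
    """Elevated homicide masking — stresses the population-adjustment assumption."""
    return MaskingRule(
        base={CauseClass.NTA: base, CauseClass.SUI: base, CauseClass.HOM: hom},
        scenario="hidden_homicide",
    )


def covariate_modulated_masking(
    base: Mapping[CauseClass, float], modulators: Mapping[str, Mapping[str, float]]
) -> MaskingRule:
    return MaskingRule(
        base={c: float(base[c]) for c in KNOWN_CAUSES},
        modulators={f: dict(m) for f, m in modulators.items()},
        scenario="covariate_modulated",
    )


@dataclasses.dataclass
class GeneratorConfig:
    """Full description of one synthetic microdata draw."""

    n_records: int
    cause_mix: Dict[CauseClass, float]
    sex_dist: Dict[CauseClass, Dict[str, float]]
    covariate_dists: Dict[CauseClass, Dict[str, Dict[str, float]]]
    masking: MaskingRule
    seed: int = 0
    schema: Schema = dataclasses.field(default_factory=default_schema)
    # annual population denominators: sex -> known age group -> persons
    population: Optional[Dict[str, Dict[str, float]]] = None

    def validate(self) -> None:
        if self.n_records < 0:
            raise ConfigError("n_records must be nonnegative")
        _check_dist("cause_mix", {c.name: p for c, p in self.cause_mix.items()})
        if set(self.cause_mix) != set(KNOWN_CAUSES):
            raise ConfigError("cause_mix must cover exactly NTA, SUI, HOM")
        for cause in KNOWN_CAUSES:
            _check_dist(f"sex_dist[{cause.name}]", self.sex_dist[cause])
            dists = self.covariate_dists[cause]
            for field in COVARIATE_FIELDS:
                if field not in dists:
                    raise ConfigError(f"{cause.name}: no distribution for {field}")
                _check_dist(f"{cause.name}.{field}", dists[field])
                for level in dists[field]:
                    self.schema.validate_value(field, str(level))
        self.masking.validate()


def _sample_levels(rng, levels: Sequence[str], probs: Sequence[float], size: int):
    idx = rng.choice(len(levels), size=size, p=np.asarray(probs, float) / np.sum(probs))
    return np.asarray(levels, dtype=object)[idx]


def generate(config: GeneratorConfig):
    """Draw microdata and its ground truth.

    Returns ``(frame, truth)`` where ``frame`` follows the records_io CSV
    schema (``cause_class`` is EUI for masked records) and ``truth`` pairs
    each ``record_id`` with its latent true cause.  Identical seeds give
    identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_records
    mix = np.array([config.cause_mix[c] for c in KNOWN_CAUSES], float)
    true_idx = rng.choice(3, size=n, p=mix / mix.sum())

    columns: Dict[str, np.ndarray] = {
        "sex": np.empty(n, dtype=object),
    }
    for field in COVARIATE_FIELDS:
        columns[field] = np.empty(n, dtype=object)

    for ci, cause in enumerate(KNOWN_CAUSES):
        idx = np.flatnonzero(true_idx == ci)
        if idx.size == 0:
            continue
        sdist = config.sex_dist[cause]
        columns["sex"][idx] = _sample_levels(
            rng, list(sdist.keys()), list(sdist.values()), idx.size
        )
        for field in COVARIATE_FIELDS:
            dist = config.covariate_dists[cause][field]
            columns[field][idx] = _sample_levels(
                rng, [str(k) for k in dist.keys()], list(dist.values()), idx.size
            )

    frame = pd.DataFrame(columns)
    mask_p = config.masking.probabilities(true_idx, frame)
    masked = rng.random(n) < mask_p

    true_names = np.array([c.name for c in KNOWN_CAUSES], dtype=object)[true_idx]
    observed = np.where(masked, "EUI", true_names)
    width = max(6, len(str(max(n, 1))))
    frame.insert(0, "record_id", [f"r{i:0{width}d}" for i in range(n)])
    frame["cause_class"] = observed
    for col in ("icd_external", "icd_injury", "certifier", "death_location"):
        frame[col] = ""
    truth = pd.DataFrame({"record_id": frame["record_id"], "true_cause": true_names})
    return frame, truth


def population_frame(config: GeneratorConfig) -> pd.DataFrame:
    """Generator-declared denominators as a tidy (sex, year, age_group) table."""
    if config.population is None:
        raise ConfigError("config declares no population denominators")
    rows = []
    for sex in SEXES:
        for year in config.schema.levels["year"]:
            for age in KNOWN_AGE_GROUPS:
                rows.append(
                    {
                        "sex": sex,
                        "year": year,
                        "age_group": age,
                        "population": float(config.population[sex][age]),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Bundled default configuration
# ---------------------------------------------------------------------------

# Registry-scale cause mix 1481:541:379 (thousands), EUI share ~0.15.
_MIX_RAW = {CauseClass.NTA: 1481.0, CauseClass.SUI: 541.0, CauseClass.HOM: 379.0}

_INJURY_P = {
    # 19-vector per cause; sharply cause-specific so the classifier has signal
    CauseClass.NTA: [.05, .10, .04, .01, .005, .02, .02, .08, .02, .07,
                     .015, .02, .16, .08, .10, .09, .03, .08, .01],
    CauseClass.SUI: [.01, .02, .01, .04, .03, .01, .02, .06, .005, .01,
                     .002, .06, .02, .04, .10, .005, .45, .013, .095],
    CauseClass.HOM: [.12, .20, .06, .07, .22, .04, .07, .04, .001, .01,
                     .001, .003, .005, .002, .01, .002, .05, .006, .09],
}

_AGE_P = {
    CauseClass.NTA: [.03, .08, .13, .17, .18, .16, .22, .03],
    CauseClass.SUI: [.01, .12, .16, .17, .17, .15, .20, .02],
    CauseClass.HOM: [.02, .10, .20, .22, .20, .13, .08, .05],
}

_PLACE_P = {
    CauseClass.NTA: [.45, .03, .02, .01, .17, .03, .14, .15],
    CauseClass.SUI: [.62, .04, .02, .005, .08, .015, .12, .10],
    CauseClass.HOM: [.35, .02, .02, .005, .28, .03, .14, .155],
}

_REGION_P = {
    CauseClass.NTA: [.16, .13, .12, .11, .11, .10, .10, .09, .08],
    CauseClass.SUI: [.10, .12, .13, .12, .11, .11, .11, .10, .10],
    CauseClass.HOM: [.14, .10, .10, .10, .12, .12, .11, .11, .10],
}

_YEAR_P = {
    CauseClass.NTA: [.36, .33, .31],
    CauseClass.SUI: [.34, .33, .33],
    CauseClass.HOM: [.38, .33, .29],
}

_SIMPLE_P = {
    "identity_known": {CauseClass.NTA: [.97, .03], CauseClass.SUI: [.99, .01],
                       CauseClass.HOM: [.90, .10]},
    "day_type": {CauseClass.NTA: [.18, .82], CauseClass.SUI: [.22, .78],
                 CauseClass.HOM: [.20, .80]},
    "season": {CauseClass.NTA: [.30, .22, .48], CauseClass.SUI: [.22, .30, .48],
               CauseClass.HOM: [.26, .26, .48]},
    "urban_rural": {CauseClass.NTA: [.72, .28], CauseClass.SUI: [.60, .40],
                    CauseClass.HOM: [.70, .30]},
    "alcohol": {CauseClass.NTA: [.55, .45], CauseClass.SUI: [.35, .65],
                CauseClass.HOM: [.60, .40]},
}

_SEX_P = {CauseClass.NTA: .75, CauseClass.SUI: .82, CauseClass.HOM: .72}

_DEFAULT_POP = {
    "male": {"0-14": 11.0e6, "15-24": 9.5e6, "25-34": 11.5e6, "35-44": 9.8e6,
             "45-54": 9.6e6, "55-64": 8.0e6, "65+": 5.0e6},
    "female": {"0-14": 10.5e6, "15-24": 9.2e6, "25-34": 11.3e6, "35-44": 10.0e6,
               "45-54": 10.6e6, "55-64": 10.2e6, "65+": 9.5e6},
}


def default_russia_like_config(
    n_records: int = 50_000,
    seed: int = 0,
    masking: Optional[MaskingRule] = None,
) -> GeneratorConfig:
    """A documented config with registry-like magnitudes and strong covariate
    signal; uniform 0.15 masking unless another rule is supplied."""
    schema = default_schema()
    mix_total = sum(_MIX_RAW.values())
    cause_mix = {c: v / mix_total for c, v in _MIX_RAW.items()}

    covariate_dists: Dict[CauseClass, Dict[str, Dict[str, float]]] = {}
    sex_dist: Dict[CauseClass, Dict[str, float]] = {}
    for cause in KNOWN_CAUSES:
        sex_dist[cause] = {"male": _SEX_P[cause], "female": 1.0 - _SEX_P[cause]}
        d: Dict[str, Dict[str, float]] = {}
        d["age_group"] = dict(zip(schema.levels["age_group"], _AGE_P[cause]))
        d["injury_category"] = dict(
            zip(schema.levels["injury_category"], _INJURY_P[cause])
        )
        d["place"] = dict(zip(schema.levels["place"], _PLACE_P[cause]))
        d["region"] = dict(zip(schema.levels["region"], _REGION_P[cause]))
        d["year"] = dict(zip(schema.levels["year"], _YEAR_P[cause]))
        for field, table in _SIMPLE_P.items():
            d[field] = dict(zip(schema.levels[field], table[cause]))
        covariate_dists[cause] = d

    return GeneratorConfig(
        n_records=n_records,
        cause_mix=cause_mix,
        sex_dist=sex_dist,
        covariate_dists=covariate_dists,
        masking=masking if masking is not None else uniform_masking(0.15),
        seed=seed,
        schema=schema,
        population=_DEFAULT_POP,
    )


# ---------------------------------------------------------------------------
# YAML (de)serialization for CLI use
# ---------------------------------------------------------------------------


def config_to_yaml(config: GeneratorConfig, path) -> None:
    doc = {
        "n_records": config.n_records,
        "seed": config.seed,
        "cause_mix": {c.name: p for c, p in config.cause_mix.items()},
        "sex_dist": {c.name: dict(d) for c, d in config.sex_dist.items()},
        "covariate_dists": {
            c.name: {f: dict(d) for f, d in dists.items()}
            for c, dists in config.covariate_dists.items()
        },
        "masking": {
            "scenario": config.masking.scenario,
            "base": {c.name: p for c, p in config.masking.base.items()},
            "modulators": {f: dict(m) for f, m in config.masking.modulators.items()},
        },
        "schema": {f: list(config.schema.levels[f]) for f in COVARIATE_FIELDS},
        "population": config.population,
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def config_from_yaml(path) -> GeneratorConfig:
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    schema = Schema(levels={f: tuple(str(x) for x in doc["schema"][f])
                            for f in COVARIATE_FIELDS})
    masking = MaskingRule(
        base={CauseClass[c]: float(p) for c, p in doc["masking"]["base"].items()},
        modulators={f: {str(k): float(v) for k, v in m.items()}
                    for f, m in doc["masking"].get("modulators", {}).items()},
        scenario=doc["masking"].get("scenario", "custom"),
    )
    config = GeneratorConfig(
        n_records=int(doc["n_records"]),
        cause_mix={CauseClass[c]: float(p) for c, p in doc["cause_mix"].items()},
        sex_dist={CauseClass[c]: {str(k): float(v) for k, v in d.items()}
                  for c, d in doc["sex_dist"].items()},
        covariate_dists={
            CauseClass[c]: {f: {str(k): float(v) for k, v in d.items()}
                            for f, d in dists.items()}
            for c, dists in doc["covariate_dists"].items()
        },
        masking=masking,
        seed=int(doc.get("seed", 0)),
        schema=schema,
        population=doc.get("population"),
    )
    config.validate()
    return config
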