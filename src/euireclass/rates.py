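"""Age-specific and age-standardized death rates (SDR).

The bundled standard is the classic European standard population collapsed
to the seven known age groups used by the record schema; any other standard
aligned with those groups can be supplied instead.  Deaths of unknown age
are redistributed proportionally over known ages before rate computation.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Union

import numpy as np
import pandas as pd

from .records_io import KNOWN_AGE_GROUPS, KNOWN_CAUSES

__all__ = [
    "StandardPopulation",
    "european_standard",
    "sdr",
    "redistribute_unknown_age",
    "adjusted_and_share",
    "adjusted_series",
]

PER = 100_000.0


@dataclasses.dataclass(frozen=True)
class StandardPopulation:
    age_groups: tuple
    weights: tuple

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if (w < 0).any():
            raise ValueError("standard weights must be nonnegative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("standard weights must sum to 1")
        if len(self.age_groups) != len(self.weights):
            raise ValueError("age groups and weights must align")


# European standard population collapsed to the schema's seven age bands
# (per 100,000: 22,000 / 14,000 / 14,000 / 14,000 / 14,000 / 11,000 / 11,000).
_ESP_WEIGHTS = (0.22, 0.14, 0.14, 0.14, 0.14, 0.11, 0.11)


def european_standard() -> StandardPopulation:
    return StandardPopulation(age_groups=KNOWN_AGE_GROUPS, weights=_ESP_WEIGHTS)


def _as_series(values, age_groups) -> pd.Series:
    if isinstance(values, pd.Series):
        return values.astype(float)
    if isinstance(values, Mapping):
        return pd.Series({str(k): float(v) for k, v in values.items()})
    arr = np.asarray(values, dtype=float)
    return pd.Series(arr, index=list(age_groups))


def sdr(
    deaths: Union[Mapping, pd.Series, np.ndarray],
    population: Union[Mapping, pd.Series, np.ndarray],
    standard: StandardPopulation,
) -> float:
    """Age-standardized death rate per 100,000: ``sum_a w_a d_a/p_a * 1e5``."""
    d = _as_series(deaths, standard.age_groups).reindex(standard.age_groups)
    p = _as_series(population, standard.age_groups).reindex(standard.age_groups)
    d = d.fillna(0.0)
    if p.isna().any():
        missing = list(p.index[p.isna()])
        raise ValueError(f"population missing for age groups {missing}")
    bad = (p <= 0) & (d > 0)
    if bad.any():
        raise ZeroDivisionError(
            f"zero population with nonzero deaths in {list(p.index[bad])}"
        )
    rates = np.where(p.to_numpy() > 0, d.to_numpy() / np.where(p > 0, p, 1.0), 0.0)
    w = np.asarray(standard.weights, dtype=float)
    return float((w * rates).sum() * PER)


def redistribute_unknown_age(deaths_by_age: Union[Mapping, pd.Series]) -> pd.Series:
    """Spread 'unknown'-age deaths proportionally over known age groups.

    With no known-age deaths the unknown mass is spread uniformly.
    """
    s = _as_series(deaths_by_age, KNOWN_AGE_GROUPS)
    unknown = float(s.get("unknown", 0.0))
    known = s.reindex(KNOWN_AGE_GROUPS).fillna(0.0)
    if unknown <= 0:
        return known
    total = known.sum()
    if total > 0:
        return known + unknown * known / total
    return known + unknown / len(known)


def adjusted_and_share(official_sdr: float, contribution_sdr: float):
    """Adjusted SDR = official + reclassified-EUI contribution; share is the
    contribution's fraction of the adjusted rate."""
    if official_sdr < 0 or contribution_sdr < 0:
        raise ValueError("rates must be nonnegative")
    adjusted = official_sdr + contribution_sdr
    share = contribution_sdr / adjusted if adjusted > 0 else 0.0
    return adjusted, share


def _sdr_from_counts(group: pd.DataFrame, pop: pd.Series,
                     standard: StandardPopulation) -> float:
    deaths = group.groupby("age_group")["deaths"].sum()
    deaths = redistribute_unknown_age(deaths)
    return sdr(deaths, pop, standard)


def adjusted_series(
    official: pd.DataFrame,
    eui_contribution: pd.DataFrame,
    population: pd.DataFrame,
    standard: StandardPopulation = None,
) -> pd.DataFrame:
    """Annual per-sex, per-cause SDR table with official, EUI-contribution
    and adjusted variants plus the reclassified share of the adjusted rate.

    ``official`` and ``eui_contribution`` are tidy death-count tables with
    columns (sex, year, cause, age_group, deaths); ``population`` has
    columns (sex, year, age_group, population).
    """
    if standard is None:
        standard = european_standard()
    for name, df, cols in (
        ("official", official, {"sex", "year", "cause", "age_group", "deaths"}),
        ("eui_contribution", eui_contribution,
         {"sex", "year", "cause", "age_group", "deaths"}),
        ("population", population, {"sex", "year", "age_group", "population"}),
    ):
        missing = cols - set(df.columns)
        if missing:
            raise ValueError(f"{name} table missing columns {sorted(missing)}")

    official = official.assign(year=official["year"].astype(str))
    eui_contribution = eui_contribution.assign(
        year=eui_contribution["year"].astype(str)
    )
    population = population.assign(year=population["year"].astype(str))

    pop_idx = (
        population.set_index(["sex", "year", "age_group"])["population"].sort_index()
    )
    causes = [c.name for c in KNOWN_CAUSES]
    rows = []
    keys = sorted(
        set(map(tuple, official[["sex", "year"]].drop_duplicates().to_numpy()))
        | set(map(tuple, eui_contribution[["sex", "year"]].drop_duplicates().to_numpy()))
    )
    for sex, year in keys:
        try:
            pop = pop_idx.loc[(sex, year)]
        except KeyError:
            raise ValueError(f"no population for sex={sex}, year={year}") from None
        for cause in causes:
            off = official[
                (official["sex"] == sex)
                & (official["year"] == year)
                & (official["cause"] == cause)
            ]
            eui = eui_contribution[
                (eui_contribution["sex"] == sex)
                & (eui_contribution["year"] == year)
                & (eui_contribution["cause"] == cause)
            ]
            off_sdr = _sdr_from_counts(off, pop, standard) if len(off) else 0.0
            eui_sdr = _sdr_from_counts(eui, pop, standard) if len(eui) else 0.0
            adj, share = adjusted_and_share(off_sdr, eui_sdr)
            rows.append(
                {
                    "sex": sex,
                    "year": year,
                    "cause": cause,
                    "official_sdr": off_sdr,
                    "eui_sdr": eui_sdr,
                    "adjusted_sdr": adj,
                    "eui_share": share,
                }
            )
    return pd.DataFrame(rows)
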