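"""Coefficient-perturbation robustness check.

Each replicate perturbs every non-base coefficient independently by a
standard-normal draw scaled by its standard error, re-scores the records,
and compares the perturbed argmax cause with the original one.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Union

import numpy as np
import pandas as pd

from .mlogit_core import MlogitModel, softmax_scores

__all__ = ["BootstrapReport", "perturb", "stability_analysis"]

DEFAULT_N_REPLICATES = 250


def perturb(
    model: MlogitModel, seed: Union[int, np.random.Generator]
) -> np.ndarray:
    """One perturbed coefficient matrix ``B + SE * gamma`` (base row stays 0)."""
    if model.se is None or not np.isfinite(model.se).all():
        raise ValueError("model has no usable standard errors")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    gamma = rng.standard_normal(model.coef.shape)
    coef = model.coef + model.se * gamma
    coef[model.base_index] = 0.0
    return coef


@dataclasses.dataclass
class BootstrapReport:
    """Per-record and overall agreement between perturbed and original
    predictions, plus the minimal ECP above which every replicate agreed."""

    n_replicates: int
    seed: int
    agreement_fraction: np.ndarray   # per record, in [0, 1]
    original_max_ecp: np.ndarray
    overall_share: float
    threshold: Optional[float]       # None when no level guarantees agreement

    def __post_init__(self) -> None:
        if not (0.0 <= self.overall_share <= 1.0):
            raise ValueError("agreement share must lie in [0, 1]")
        if self.threshold is not None and not (
            1.0 / 3.0 - 1e-9 <= self.threshold <= 1.0
        ):
            raise ValueError("threshold must lie in [1/3, 1] or be None")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "original_max_ecp": self.original_max_ecp,
                "agreement_fraction": self.agreement_fraction,
            }
        )

    def summary(self) -> dict:
        return {
            "n_replicates": self.n_replicates,
            "seed": self.seed,
            "overall_agreement_share": self.overall_share,
            "share_fully_stable": float((self.agreement_fraction == 1.0).mean()),
            "stability_ecp_threshold": self.threshold,
        }


def stability_analysis(
    model: MlogitModel,
    X: np.ndarray,
    n_replicates: int = DEFAULT_N_REPLICATES,
    seed: int = 0,
) -> BootstrapReport:
    """Run the perturbation check on encoded records.

    The reported threshold is the smallest original max-ECP value t such
    that every record with max-ECP >= t agreed with the original prediction
    in all replicates (1/3 when all records agree, ``None`` when even the
    most confident record disagreed somewhere).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be at least 1")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    rng = np.random.default_rng(seed)

    probs = model.predict_proba(X)
    original = probs.argmax(axis=1)
    max_ecp = probs.max(axis=1)

    agree_counts = np.zeros(len(X), dtype=np.int64)
    for _ in range(n_replicates):
        coef = perturb(model, rng)
        scores = X @ coef.T
        agree_counts += scores.argmax(axis=1) == original

    agreement = agree_counts / n_replicates
    all_agree = agreement == 1.0
    if all_agree.all():
        threshold: Optional[float] = 1.0 / 3.0
    else:
        worst_disagree = float(max_ecp[~all_agree].max())
        above = max_ecp[max_ecp > worst_disagree]
        threshold = float(above.min()) if above.size else None

    return BootstrapReport(
        n_replicates=n_replicates,
        seed=seed,
        agreement_fraction=agreement,
        original_max_ecp=max_ecp,
        overall_share=float(agreement.mean()),
        threshold=threshold,
    )
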