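"""Class-weighted multinomial logistic model and estimated classification
probabilities (ECPs).

The model for record ``n`` with indicator vector ``x^n`` is

    Pr(n, cause=i) = exp(sum_k B_ik x_k^n) / sum_i exp(sum_k B_ik x_k^n)

with one outcome fixed as the base (its coefficient row identically zero).
Coefficients maximize the case-weighted log-likelihood via a Newton-type
optimizer with step halving; standard errors come from the observed
information at the optimum.  Class weights ``w_c = N / (K * N_c)`` equalize
the weighted class totals so estimation does not favour the largest cause.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.linalg

from .records_io import KNOWN_CAUSES, CauseClass, EncodingMap

__all__ = [
    "MlogitModel",
    "ECPVector",
    "SingularityError",
    "ConvergenceError",
    "SeparationWarning",
    "compute_class_weights",
    "fit",
    "fit_frame",
    "predict_ecp",
    "fit_transport_discriminator",
    "softmax_scores",
]


class SingularityError(np.linalg.LinAlgError):
    pass


class ConvergenceError(RuntimeError):
    pass


class SeparationWarning(UserWarning):
    pass


def compute_class_weights(labels) -> Dict:
    """Balancing weights ``w_c = N_total / (K * N_c)``.

    ``labels`` may be a sequence of class labels or a mapping label -> count.
    Weighted class totals are all equal and sum to ``N_total``.
    """
    if isinstance(labels, Mapping):
        counts = {k: int(v) for k, v in labels.items()}
    else:
        counts = {}
        for lab in labels:
            counts[lab] = counts.get(lab, 0) + 1
    k = len(counts)
    total = sum(counts.values())
    for lab, c in counts.items():
        if c == 0:
            raise ValueError(f"class {lab!r} has zero records")
    return {lab: total / (k * c) for lab, c in counts.items()}


def softmax_scores(scores: np.ndarray) -> np.ndarray:
    """Row-wise softmax, shifted by the row max for numerical stability."""
    s = scores - scores.max(axis=-1, keepdims=True)
    e = np.exp(s)
    return e / e.sum(axis=-1, keepdims=True)


@dataclasses.dataclass
class ECPVector:
    """Estimated classification probabilities for one record, with the linear
    scores that produced them."""

    probs: np.ndarray
    scores: np.ndarray
    classes: tuple = tuple(c.name for c in KNOWN_CAUSES)

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.scores = np.asarray(self.scores, dtype=float)
        k = len(self.classes)
        if self.probs.shape != (k,):
            raise ValueError("probability vector has wrong length")
        if (self.probs < -1e-12).any() or (self.probs > 1 + 1e-12).any():
            raise ValueError("probabilities outside [0, 1]")
        if abs(self.probs.sum() - 1.0) > 1e-9:
            raise ValueError("probabilities do not sum to 1")
        if self.probs.max() < 1.0 / k - 1e-9:
            raise ValueError("max probability below 1/K")

    @property
    def max_prob(self) -> float:
        return float(self.probs.max())

    @property
    def argmax(self) -> int:
        return int(np.argmax(self.probs))


@dataclasses.dataclass
class MlogitModel:
    """Fitted multinomial logistic model (base-outcome row fixed at zero)."""

    classes: tuple
    base_index: int
    coef: np.ndarray        # (K, p); base row identically 0
    se: np.ndarray          # (K, p); base row 0
    columns: tuple
    class_weights: Optional[Dict] = None
    encoding: Optional[EncodingMap] = None
    converged: bool = True
    n_iter: int = 0
    final_grad_norm: float = np.nan
    loglike: float = np.nan

    def __post_init__(self) -> None:
        self.coef = np.asarray(self.coef, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        if not np.allclose(self.coef[self.base_index], 0.0):
            raise ValueError("base-outcome coefficient row must be zero")
        nonbase = [i for i in range(len(self.classes)) if i != self.base_index]
        if not np.isfinite(self.se[nonbase]).all() or (self.se[nonbase] < 0).any():
            raise ValueError("standard errors must be finite and nonnegative")

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def linear_scores(self, X: np.ndarray) -> np.ndarray:
        return np.atleast_2d(X) @ self.coef.T

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return softmax_scores(self.linear_scores(X))

    # -- text serialization (JSON round-trips Python floats exactly) --------

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "base_index": self.base_index,
            "coef": self.coef.tolist(),
            "se": self.se.tolist(),
            "columns": list(self.columns),
            "class_weights": self.class_weights,
            "encoding": self.encoding.to_dict() if self.encoding else None,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "final_grad_norm": self.final_grad_norm,
            "loglike": self.loglike,
        }

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "MlogitModel":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(
            classes=tuple(d["classes"]),
            base_index=d["base_index"],
            coef=np.array(d["coef"], dtype=float),
            se=np.array(d["se"], dtype=float),
            columns=tuple(d["columns"]),
            class_weights=d.get("class_weights"),
            encoding=EncodingMap.from_dict(d["encoding"]) if d.get("encoding") else None,
            converged=d.get("converged", True),
            n_iter=d.get("n_iter", 0),
            final_grad_norm=d.get("final_grad_norm", np.nan),
            loglike=d.get("loglike", np.nan),
        )


def _collinear_columns(X: np.ndarray, columns: Sequence[str]) -> list:
    q, r, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    return [columns[j] for j in sorted(piv[rank:])]


def _weighted_loglike(scores, y, w):
    shifted = scores - scores.max(axis=1, keepdims=True)
    lse = np.log(np.exp(shifted).sum(axis=1)) + scores.max(axis=1)
    return float(np.sum(w * (scores[np.arange(len(y)), y] - lse)))


def fit(
    X: np.ndarray,
    y: np.ndarray,
    sample_weight: Optional[np.ndarray] = None,
    classes: Optional[Sequence] = None,
    base_index: Optional[int] = None,
    columns: Optional[Sequence[str]] = None,
    encoding: Optional[EncodingMap] = None,
    class_weights: Optional[Dict] = None,
    max_iter: int = 200,
    grad_tol: float = 1e-6,
    ll_tol: float = 1e-10,
) -> MlogitModel:
    """Maximum-likelihood fit of the K-class model.

    ``y`` holds integer class indices 0..K-1.  Deterministic: zero start
    values, Newton steps with step halving, convergence when the gradient
    max-norm drops below ``grad_tol`` or the relative log-likelihood change
    below ``ll_tol``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n, p = X.shape
    if classes is None:
        classes = tuple(c.name for c in KNOWN_CAUSES)
    k = len(classes)
    if len(np.unique(y)) < 2:
        raise ValueError("need at least two observed outcome classes")
    if base_index is None:
        base_index = k - 1
    if columns is None:
        columns = tuple(f"x{j}" for j in range(p))
    columns = tuple(columns)
    w = np.ones(n) if sample_weight is None else np.asarray(sample_weight, float)

    if np.linalg.matrix_rank(X) < p:
        bad = _collinear_columns(X, columns)
        raise SingularityError(
            f"design matrix is rank deficient; collinear columns: {bad}"
        )

    free = [i for i in range(k) if i != base_index]
    B = np.zeros((k, p))
    onehot = np.zeros((n, k))
    onehot[np.arange(n), y] = 1.0

    ll = _weighted_loglike(X @ B.T, y, w)
    grad_norm = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        P = softmax_scores(X @ B.T)
        G = np.stack([X.T @ (w * (onehot[:, a] - P[:, a])) for a in free])
        grad_norm = float(np.abs(G).max())
        if grad_norm < grad_tol:
            break

        nf = len(free)
        H = np.zeros((nf * p, nf * p))
        for ia, a in enumerate(free):
            for ib, b in enumerate(free):
                if ib < ia:
                    continue
                wab = w * P[:, a] * ((1.0 if a == b else 0.0) - P[:, b])
                block = X.T @ (X * wab[:, None])
                H[ia * p:(ia + 1) * p, ib * p:(ib + 1) * p] = block
                if ib != ia:
                    H[ib * p:(ib + 1) * p, ia * p:(ia + 1) * p] = block
        # H is the observed information (negative log-likelihood Hessian), SPD
        neg_h = H
        try:
            cho = scipy.linalg.cho_factor(neg_h)
            step = scipy.linalg.cho_solve(cho, G.ravel())
        except np.linalg.LinAlgError:
            # near-singular curvature (e.g. separation): ridge fallback
            ridge = 1e-8 * np.trace(neg_h) / neg_h.shape[0]
            step = scipy.linalg.solve(
                neg_h + ridge * np.eye(neg_h.shape[0]), G.ravel(),
                assume_a="pos",
            )
        step = step.reshape(nf, p)

        scale = 1.0
        new_ll = -np.inf
        for _ in range(40):
            B_try = B.copy()
            for ia, a in enumerate(free):
                B_try[a] = B[a] + scale * step[ia]
            new_ll = _weighted_loglike(X @ B_try.T, y, w)
            if new_ll >= ll - 1e-12 * max(1.0, abs(ll)):
                break
            scale *= 0.5
        if new_ll < ll - 1e-8 * max(1.0, abs(ll)):
            raise ConvergenceError(
                f"step halving failed at iteration {it} "
                f"(ll {ll:.6f} -> {new_ll:.6f}, grad norm {grad_norm:.3e})"
            )
        improved = new_ll - ll
        B = B_try
        ll = new_ll
        if abs(improved) < ll_tol * max(1.0, abs(ll)):
            P = softmax_scores(X @ B.T)
            G = np.stack([X.T @ (w * (onehot[:, a] - P[:, a])) for a in free])
            grad_norm = float(np.abs(G).max())
            break
    else:
        raise ConvergenceError(
            f"no convergence after {max_iter} iterations "
            f"(grad norm {grad_norm:.3e})"
        )

    big = np.abs(B) > 15.0
    if big.any():
        bad_cols = sorted({columns[j] for j in np.where(big.any(axis=0))[0]})
        warnings.warn(
            "possible quasi-complete separation; very large coefficients on "
            f"indicators: {bad_cols}",
            SeparationWarning,
            stacklevel=2,
        )

    # observed information at the optimum -> standard errors
    P = softmax_scores(X @ B.T)
    nf = len(free)
    H = np.zeros((nf * p, nf * p))
    for ia, a in enumerate(free):
        for ib, b in enumerate(free):
            if ib < ia:
                continue
            wab = w * P[:, a] * ((1.0 if a == b else 0.0) - P[:, b])
            block = X.T @ (X * wab[:, None])
            H[ia * p:(ia + 1) * p, ib * p:(ib + 1) * p] = block
            if ib != ia:
                H[ib * p:(ib + 1) * p, ia * p:(ia + 1) * p] = block
    se = np.zeros((k, p))
    try:
        cov = scipy.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = scipy.linalg.pinv(H)
    diag = np.clip(np.diag(cov), 0.0, None)
    for ia, a in enumerate(free):
        se[a] = np.sqrt(diag[ia * p:(ia + 1) * p])

    return MlogitModel(
        classes=tuple(classes),
        base_index=base_index,
        coef=B,
        se=se,
        columns=columns,
        class_weights=class_weights,
        encoding=encoding,
        converged=True,
        n_iter=it,
        final_grad_norm=grad_norm,
        loglike=ll,
    )


def fit_frame(
    frame: pd.DataFrame,
    encoding: EncodingMap,
    weighted: bool = True,
    base: CauseClass = CauseClass.HOM,
    **kwargs,
) -> MlogitModel:
    """Fit on a microdata frame of known-cause deaths (typically one sex).

    Class-balancing weights are applied unless ``weighted=False``.
    """
    known = frame[frame["cause_class"].isin([c.name for c in KNOWN_CAUSES])]
    if len(known) < len(frame):
        raise ValueError("training frame contains non-known-cause records")
    y = known["cause_class"].map({c.name: c.index for c in KNOWN_CAUSES}).to_numpy()
    X = encoding.encode_frame(known)
    class_weights = None
    sample_weight = None
    if weighted:
        if len(np.unique(y)) < 3:
            raise ValueError("all three causes must be present to compute weights")
        class_weights = compute_class_weights(known["cause_class"].tolist())
        sample_weight = known["cause_class"].map(class_weights).to_numpy(float)
    return fit(
        X,
        y,
        sample_weight=sample_weight,
        classes=tuple(c.name for c in KNOWN_CAUSES),
        base_index=base.index,
        columns=encoding.columns,
        encoding=encoding,
        class_weights=class_weights,
        **kwargs,
    )


def predict_ecp(model: MlogitModel, x: np.ndarray) -> ECPVector:
    """ECP vector for one encoded record."""
    x = np.asarray(x, dtype=float)
    if x.shape != (model.coef.shape[1],):
        raise ValueError(
            f"indicator vector of length {x.shape} does not match model "
            f"({model.coef.shape[1]} columns)"
        )
    scores = model.coef @ x
    return ECPVector(probs=softmax_scores(scores), scores=scores,
                     classes=tuple(model.classes))


def fit_transport_discriminator(
    X: np.ndarray,
    is_transport: np.ndarray,
    columns: Optional[Sequence[str]] = None,
    weighted: bool = True,
    **kwargs,
) -> MlogitModel:
    """Binary model separating transport deaths from the combined
    NTA/SUI/HOM group; class 0 is transport, class 1 the rest."""
    is_transport = np.asarray(is_transport, dtype=bool)
    if is_transport.all() or (~is_transport).all():
        raise ValueError("need both transport and non-transport records")
    y = np.where(is_transport, 0, 1)
    sample_weight = None
    class_weights = None
    if weighted:
        class_weights = compute_class_weights(y.tolist())
        sample_weight = np.array([class_weights[v] for v in y], dtype=float)
    return fit(
        X,
        y,
        sample_weight=sample_weight,
        classes=("TRANSPORT", "OTHER"),
        base_index=1,
        columns=columns,
        class_weights={str(k): v for k, v in (class_weights or {}).items()} or None,
        **kwargs,
    )
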