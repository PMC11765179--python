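"""Polynomial response-surface surrogate with AIC order selection.

The model is ordinary least squares on all monomials of the four
features up to a total degree n (C(n+4, 4) terms).  Features are
standardized (center/scale learned from the training split) before
expansion: degree-4 powers of a shear rate spanning 0.1–100 1/s would
otherwise produce a catastrophically ill-conditioned design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .features import FEATURE_NAMES, N_FEATURES, multi_indices, poly_expand

__all__ = ["PolynomialModel", "fit_polynomial", "select_order_aic"]


class RankDeficientDesignError(ValueError):
    """The expanded design matrix does not have full column rank."""


def _term_name(ix: tuple[int, ...]) -> str:
    parts = [
        f"{name}^{p}" if p > 1 else name
        for name, p in zip(FEATURE_NAMES, ix)
        if p > 0
    ]
    return "*".join(parts) if parts else "1"


@dataclass
class PolynomialModel:
    """Fitted polynomial surrogate of ln-viscosity."""

    degree: int
    coefficients: np.ndarray  # aligned with multi_indices(degree)
    center: np.ndarray  # per-feature standardization offset
    scale: np.ndarray  # per-feature standardization divisor
    rss: float = 0.0
    n_train: int = 0
    rank: int = 0  # numerical rank of the training design
    indices: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.indices:
            self.indices = multi_indices(self.degree)
        if len(self.coefficients) != len(self.indices):
            raise ValueError("coefficient count does not match the term count")

    @property
    def coefficient_map(self) -> dict[tuple[int, ...], float]:
        """Coefficients keyed by (i, j, k, l) exponent tuples."""
        return {tuple(ix): float(b) for ix, b in zip(self.indices, self.coefficients)}

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Z = (X - self.center) / self.scale
        return poly_expand(Z, self.degree) @ self.coefficients

    def to_dict(self) -> dict:
        return {
            "kind": "poly",
            "degree": self.degree,
            "coefficients": {
                ",".join(map(str, ix)): float(b)
                for ix, b in zip(self.indices, self.coefficients)
            },
            "center": self.center.tolist(),
            "scale": self.scale.tolist(),
            "rss": self.rss,
            "n_train": self.n_train,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PolynomialModel":
        indices = multi_indices(d["degree"])
        coefs = np.array([d["coefficients"][",".join(map(str, ix))] for ix in indices])
        return cls(
            degree=d["degree"],
            coefficients=coefs,
            center=np.asarray(d["center"], dtype=float),
            scale=np.asarray(d["scale"], dtype=float),
            rss=d.get("rss", 0.0),
            n_train=d.get("n_train", 0),
            indices=indices,
        )


def fit_polynomial(
    X: np.ndarray,
    y: np.ndarray,
    degree: int = 4,
    standardize: bool = True,
    require_full_rank: bool = False,
) -> PolynomialModel:
    """Least squares on the expanded (optionally standardized) design.

    The canonical eight-composition design is structurally rank-deficient
    at degree 4 — the compositions lie on the plane A + G + T = 8 and
    only eight distinct (A, G, T) points exist — so by default the
    minimum-norm least-squares solution is used, which is deterministic
    and predicts correctly on the span of the training design.  With
    ``require_full_rank=True`` a rank-deficient design instead raises
    :class:`RankDeficientDesignError` naming the degenerate terms.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    indices = multi_indices(degree)
    n_terms = len(indices)
    if X.shape[0] < n_terms:
        raise ValueError(
            f"degree {degree} needs at least {n_terms} training points, got {X.shape[0]}"
        )

    if standardize:
        center = X.mean(axis=0)
        scale = X.std(axis=0)
        scale[scale == 0] = 1.0
    else:
        center = np.zeros(N_FEATURES)
        scale = np.ones(N_FEATURES)
    Z = (X - center) / scale
    design = poly_expand(Z, degree)

    coefs, residuals, rank, sv = np.linalg.lstsq(design, y, rcond=None)
    if rank < n_terms and require_full_rank:
        # name the terms whose columns fall in the (numerical) null space
        _, _, vt = np.linalg.svd(design, full_matrices=False)
        null_weight = np.abs(vt[rank:]).sum(axis=0)
        bad = [
            _term_name(indices[i])
            for i in np.argsort(null_weight)[::-1][: n_terms - rank]
        ]
        raise RankDeficientDesignError(
            f"rank-deficient polynomial design (rank {rank} < {n_terms}); "
            f"degenerate term(s): {bad}"
        )
    rss = float(np.sum((design @ coefs - y) ** 2))
    return PolynomialModel(
        degree, coefs, center, scale, rss=rss, n_train=len(y), rank=int(rank),
        indices=indices,
    )


def select_order_aic(
    X: np.ndarray,
    y: np.ndarray,
    candidate_degrees=(1, 2, 3, 4, 5),
) -> tuple[int, dict[int, float]]:
    """Pick the polynomial degree minimizing AIC = N ln(RSS/N) + 2p.

    This is the Gaussian least-squares form of the criterion with p the
    number of regression coefficients.  Candidates whose term count
    reaches the sample size are excluded with a warning.  Returns the
    selected degree and the per-degree AIC scores; ties go to the lower
    degree.
    """
    candidates = sorted(set(candidate_degrees))
    if not candidates:
        raise ValueError("need at least one candidate degree")
    y = np.asarray(y, dtype=float)
    n = y.size
    scores: dict[int, float] = {}
    for d in candidates:
        p = len(multi_indices(d))
        if p >= n:
            warnings.warn(
                f"degree {d} excluded: {p} terms >= {n} observations", stacklevel=2
            )
            continue
        model = fit_polynomial(X, y, degree=d)
        rss = max(model.rss, 1e-300)
        scores[d] = n * np.log(rss / n) + 2 * p
    if not scores:
        raise ValueError("no candidate degree is estimable with this sample size")
    best = min(scores, key=lambda d: (scores[d], d))
    return best, scores
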