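"""Surrogate evaluation: R²/MAE metrics and repeated random holdout.

All metrics are computed in ln-viscosity units — the scale the
surrogates are trained on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .forest import fit_forest
from .polynomial import fit_polynomial
from .tree import fit_tree

__all__ = ["EvalReport", "evaluate", "repeated_holdout", "make_surrogate_factory"]


@dataclass
class EvalReport:
    r2: float
    mae: float
    n_train: int
    n_test: int
    per_iteration: list[dict] = field(default_factory=list)

    @property
    def r2_per_iter(self) -> list[float]:
        return [it["r2"] for it in self.per_iteration]

    @property
    def mae_per_iter(self) -> list[float]:
        return [it["mae"] for it in self.per_iteration]

    def to_dict(self) -> dict:
        return {
            "r2_mean": self.r2,
            "mae_mean": self.mae,
            "n_train": self.n_train,
            "n_test": self.n_test,
            "r2_per_iter": self.r2_per_iter,
            "mae_per_iter": self.mae_per_iter,
        }


def evaluate(model, X_test: np.ndarray, y_test: np.ndarray, n_train: int = 0) -> EvalReport:
    """R² = 1 - SS_res/SS_tot and MAE = mean |error| on a test set."""
    X_test = np.atleast_2d(np.asarray(X_test, dtype=float))
    y_test = np.asarray(y_test, dtype=float)
    if y_test.size == 0:
        raise ValueError("test set is empty")
    pred = model.predict(X_test)
    ss_tot = float(np.sum((y_test - y_test.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("R^2 undefined: test targets have zero variance")
    ss_res = float(np.sum((y_test - pred) ** 2))
    mae = float(np.mean(np.abs(y_test - pred)))
    return EvalReport(r2=1.0 - ss_res / ss_tot, mae=mae, n_train=n_train, n_test=y_test.size)


def make_surrogate_factory(kind: str, **kwargs):
    """Factory ``fit(X, y, seed) -> model`` for 'poly', 'tree' or 'forest'.

    Keyword arguments are forwarded to the underlying fit function
    (e.g. ``degree=4`` for the polynomial, ``n_trees=200`` for the
    forest).  Only the forest consumes the seed.
    """
    if kind == "poly":
        return lambda X, y, seed: fit_polynomial(X, y, **kwargs)
    if kind == "tree":
        return lambda X, y, seed: fit_tree(X, y, **kwargs)
    if kind == "forest":
        return lambda X, y, seed: fit_forest(X, y, seed=seed, **kwargs)
    raise ValueError(f"unknown surrogate kind {kind!r}")


def repeated_holdout(
    X: np.ndarray,
    y: np.ndarray,
    fit,
    iterations: int = 100,
    train_fraction: float = 0.8,
    seed: int = 0,
) -> EvalReport:
    """Repeated random train/test split validation.

    Each iteration draws a random permutation, trains on the first
    floor(train_fraction * N) points and evaluates on the rest (at
    N = 169 and fraction 0.8 this is the 135/34 split).  Reported R² and
    MAE are means over iterations; per-iteration metrics are kept in
    ``per_iteration``.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if not (0 < train_fraction < 1):
        raise ValueError("train_fraction must be in (0, 1)")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n = y.size
    n_train = int(np.floor(train_fraction * n))
    if n_train < 1 or n_train >= n:
        raise ValueError(f"degenerate split {n_train}/{n - n_train}")

    rng = np.random.default_rng(seed)
    per_iter = []
    for it in range(iterations):
        perm = rng.permutation(n)
        tr, te = perm[:n_train], perm[n_train:]
        model = fit(X[tr], y[tr], int(rng.integers(0, 2**31 - 1)))
        rep = evaluate(model, X[te], y[te], n_train=n_train)
        per_iter.append({"iteration": it, "r2": rep.r2, "mae": rep.mae})

    r2s = np.array([d["r2"] for d in per_iter])
    maes = np.array([d["mae"] for d in per_iter])
    return EvalReport(
        r2=float(r2s.mean()), mae=float(maes.mean()),
        n_train=n_train, n_test=n - n_train, per_iteration=per_iter,
    )
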