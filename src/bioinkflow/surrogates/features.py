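"""Feature extraction and polynomial term expansion for viscosity surrogates.

The surrogate target is the natural log of viscosity in mPa·s; features
are (shear rate, alginate wt%, gelatin wt%, TO-NFC wt%), in that order.
"""

from __future__ import annotations

from itertools import product
from math import comb

import numpy as np

FEATURE_NAMES = ("shear_rate", "A", "G", "T")
N_FEATURES = 4

__all__ = ["FEATURE_NAMES", "N_FEATURES", "log_target", "multi_indices", "poly_expand"]


def log_target(dataset) -> tuple[np.ndarray, np.ndarray]:
    """Design matrix (gamma_dot, A, G, T) and ln-viscosity targets.

    Accepts a :class:`~bioinkflow.datasets.FlowCurveDataset` or any object
    with a compatible ``frame`` attribute.
    """
    frame = dataset.frame
    eta = frame["viscosity_mPas"].to_numpy(dtype=float)
    if np.any(eta <= 0):
        raise ValueError("viscosities must be positive to take logs")
    X = frame[["shear_rate", "A", "G", "T"]].to_numpy(dtype=float)
    return X, np.log(eta)


def multi_indices(degree: int, n_vars: int = N_FEATURES) -> list[tuple[int, ...]]:
    """All exponent tuples with total degree <= ``degree``, graded lex order.

    Within each total degree, tuples are ordered lexicographically.  The
    count is C(degree + n_vars, n_vars).
    """
    if degree < 0:
        raise ValueError("degree must be >= 0")
    out: list[tuple[int, ...]] = []
    for total in range(degree + 1):
        block = [ix for ix in product(range(total + 1), repeat=n_vars) if sum(ix) == total]
        block.sort()
        out.extend(block)
    assert len(out) == comb(degree + n_vars, n_vars)
    return out


def poly_expand(points: np.ndarray, degree: int) -> np.ndarray:
    """Expand feature rows into all monomials of total degree <= ``degree``.

    Returns an (n_points, C(degree+4, 4)) term matrix whose columns follow
    :func:`multi_indices` order (constant term first).
    """
    if degree < 1:
        raise ValueError("degree must be >= 1")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[1] != N_FEATURES:
        raise ValueError(f"expected {N_FEATURES} features, got {pts.shape[1]}")
    indices = multi_indices(degree)
    # powers[v][k] = pts[:, v] ** k, computed once per variable
    max_pow = degree
    powers = [np.vander(pts[:, v], max_pow + 1, increasing=True) for v in range(N_FEATURES)]
    cols = [
        powers[0][:, i] * powers[1][:, j] * powers[2][:, k] * powers[3][:, l]
        for (i, j, k, l) in indices
    ]
    return np.column_stack(cols)
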