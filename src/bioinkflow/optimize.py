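"""Formulation optimization: penalty-constrained differential evolution.

The goal is a (shear rate, alginate, gelatin, TO-NFC) combination whose
surrogate-predicted ln-viscosity lands inside the structural-integrity
window of 100–500 Pa·s — ln 11.52 to 13.12 in mPa·s, midpoint 12.32.
The objective is the squared deviation of the prediction from the
midpoint; a penalty term activates outside the window, and an optional
quadratic shear-rate floor models high-shear printing conditions where
the nozzle-tip shear rate exceeds 50 1/s.

Note on the penalty form: a signed version (prediction minus the lower
bound, which is negative below the window and would reward undershoot)
is sometimes written down; the default here is the absolute deviation
from the violated bound, which is non-negative everywhere and zero
exactly on the feasible window.  The signed variant is available via
``signed=True``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TargetWindow",
    "SearchBounds",
    "OptResult",
    "objective",
    "penalty",
    "differential_evolution",
    "optimize_formulation",
]

#: Default structural-integrity window, ln of viscosity in mPa·s.
DEFAULT_WINDOW_LOW = 11.52
DEFAULT_WINDOW_HIGH = 13.12


@dataclass(frozen=True)
class TargetWindow:
    """Acceptable ln-viscosity band for structural integrity."""

    lower: float = DEFAULT_WINDOW_LOW
    upper: float = DEFAULT_WINDOW_HIGH

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError("window lower bound must be below upper bound")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.lower + self.upper)

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper


@dataclass(frozen=True)
class SearchBounds:
    """Per-parameter search box for (shear rate, A, G, T)."""

    shear_rate: tuple[float, float]
    A: tuple[float, float]
    G: tuple[float, float]
    T: tuple[float, float]
    shear_floor: float | None = None

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.as_dict().items():
            if not lo < hi:
                raise ValueError(f"{name}: bound min must be below max ({lo} >= {hi})")
        if self.shear_floor is not None:
            lo, hi = self.shear_rate
            if not (lo <= self.shear_floor <= hi):
                raise ValueError("shear floor must lie within the shear-rate range")

    def as_dict(self) -> dict[str, tuple[float, float]]:
        return {
            "shear_rate": self.shear_rate, "A": self.A, "G": self.G, "T": self.T,
        }

    def as_array(self) -> np.ndarray:
        return np.array([self.shear_rate, self.A, self.G, self.T], dtype=float)

    @classmethod
    def from_dataset(cls, dataset, shear_floor: float | None = None) -> "SearchBounds":
        """Observed per-parameter ranges of a flow-curve dataset.

        With a shear floor set, the shear-rate box is raised to
        [floor, max] in addition to the quadratic floor penalty.
        """
        f = dataset.frame
        rng = lambda c: (float(f[c].min()), float(f[c].max()))
        sr = rng("shear_rate")
        if shear_floor is not None:
            sr = (max(sr[0], shear_floor), sr[1])
        return cls(sr, rng("A"), rng("G"), rng("T"), shear_floor=shear_floor)


@dataclass
class OptResult:
    scenario: str
    optimum: dict[str, float]  # shear_rate, A, G, T
    eta_pred: float  # ln mPa·s at the optimum
    objective: float  # f, squared deviation from the midpoint
    penalty: float
    F: float  # f + penalty
    in_window: bool
    generations: int
    converged: bool
    best_trace: list[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario,
            "optimum": self.optimum,
            "ln_viscosity_pred": self.eta_pred,
            "viscosity_mPas": float(np.exp(self.eta_pred)),
            "in_window": self.in_window,
            "objective": self.objective,
            "penalty": self.penalty,
            "F": self.F,
            "generations": self.generations,
            "converged": self.converged,
        }


def objective(point, surrogate, window: TargetWindow = TargetWindow()) -> float:
    """Squared deviation of the surrogate prediction from the window midpoint."""
    eta_pred = float(surrogate.predict(np.atleast_2d(point))[0])
    return (eta_pred - window.midpoint) ** 2


def penalty(
    eta_pred: float,
    window: TargetWindow = TargetWindow(),
    shear_rate: float | None = None,
    shear_floor: float | None = None,
    signed: bool = False,
) -> float:
    """Out-of-window penalty, plus a quadratic shear-rate floor term.

    Default (``signed=False``): the absolute deviation from the violated
    window bound, zero inside.  With a shear floor, (floor - shear_rate)²
    is added whenever the shear rate is at or below the floor.
    """
    if eta_pred < window.lower:
        p = eta_pred - window.lower if signed else window.lower - eta_pred
    elif eta_pred > window.upper:
        p = eta_pred - window.upper
    else:
        p = 0.0
    if shear_floor is not None:
        if shear_rate is None:
            raise ValueError("shear_rate required when a shear floor is set")
        if shear_rate <= shear_floor:
            p += (shear_floor - shear_rate) ** 2
    return p


def differential_evolution(
    func,
    bounds: np.ndarray,
    popsize: int | None = None,
    mutation: float = 0.8,
    crossover: float = 0.9,
    max_generations: int = 1000,
    tol: float = 1e-8,
    seed: int = 0,
):
    """Minimize ``func`` over a box with rand/1/bin differential evolution.

    For each population member a mutant ``x_r1 + F*(x_r2 - x_r3)`` is
    built from three distinct other members, crossed over coordinate-wise
    with probability CR (one coordinate forced), clipped to the bounds,
    and accepted if it does not increase the objective (synchronous,
    generation-based selection).  Stops when the population objective
    spread falls below ``tol`` (relative to the mean absolute objective)
    or at ``max_generations``.

    ``func`` may be vectorized — accepting an (n, dim) matrix and
    returning n values — or a plain scalar function of one point; the
    vectorized form is tried first so expensive surrogates are evaluated
    one batch per generation.

    Returns ``(best_x, best_f, info)`` with the per-generation best trace
    and convergence flag in ``info``.
    """
    bounds = np.asarray(bounds, dtype=float)
    dim = bounds.shape[0]
    lo, hi = bounds[:, 0], bounds[:, 1]
    if np.any(lo >= hi):
        raise ValueError("each bound must satisfy min < max")
    if popsize is None:
        popsize = 15 * dim
    if popsize < 4:
        raise ValueError("population size must be at least 4")

    def evaluate(X: np.ndarray) -> np.ndarray:
        try:
            out = np.asarray(func(X), dtype=float)
            if out.shape == (X.shape[0],):
                return out
        except Exception:
            pass
        return np.array([float(func(x)) for x in X])

    rng = np.random.default_rng(seed)
    pop = lo + rng.random((popsize, dim)) * (hi - lo)
    fitness = evaluate(pop)
    trace = [float(fitness.min())]
    converged = False
    gen = 0
    for gen in range(1, max_generations + 1):
        r = np.empty((popsize, 3), dtype=np.int64)
        for i in range(popsize):
            idx = rng.permutation(popsize)[:4]
            r[i] = idx[idx != i][:3]
        mutants = pop[r[:, 0]] + mutation * (pop[r[:, 1]] - pop[r[:, 2]])
        cross = rng.random((popsize, dim)) < crossover
        cross[np.arange(popsize), rng.integers(dim, size=popsize)] = True
        trials = np.clip(np.where(cross, mutants, pop), lo, hi)
        f_trials = evaluate(trials)
        accept = f_trials <= fitness
        pop[accept] = trials[accept]
        fitness[accept] = f_trials[accept]
        trace.append(float(fitness.min()))
        spread = fitness.max() - fitness.min()
        if spread <= tol * (np.mean(np.abs(fitness)) + tol):
            converged = True
            break

    best = int(np.argmin(fitness))
    info = {"generations": gen, "converged": converged, "best_trace": trace}
    return pop[best].copy(), float(fitness[best]), info


def optimize_formulation(
    surrogate,
    bounds: SearchBounds,
    scenario: str = "free",
    window: TargetWindow = TargetWindow(),
    seed: int = 0,
    **de_kwargs,
) -> OptResult:
    """Optimize (shear rate, A, G, T) against the structural-integrity window.

    Scenarios: ``"free"`` (no shear constraint) and ``"highshear"``
    (shear rate at least 50 1/s, realized both as a raised lower bound
    and as the quadratic floor penalty).  Minimizes F = f + Penalty where
    f is the squared midpoint deviation.
    """
    if scenario not in ("free", "highshear"):
        raise ValueError(f"unknown scenario {scenario!r}")
    if scenario == "highshear" and bounds.shear_floor is None:
        lo, hi = bounds.shear_rate
        bounds = SearchBounds(
            (max(lo, 50.0), hi), bounds.A, bounds.G, bounds.T, shear_floor=50.0
        )
    floor = bounds.shear_floor if scenario == "highshear" else None

    def F(X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(X)
        preds = np.asarray(surrogate.predict(X), dtype=float)
        f = (preds - window.midpoint) ** 2
        pen = np.where(
            preds < window.lower, window.lower - preds,
            np.where(preds > window.upper, preds - window.upper, 0.0),
        )
        if floor is not None:
            sr = X[:, 0]
            pen = pen + np.where(sr <= floor, (floor - sr) ** 2, 0.0)
        return f + pen

    best_x, best_F, info = differential_evolution(
        F, bounds.as_array(), seed=seed, **de_kwargs
    )
    eta_pred = float(surrogate.predict(np.atleast_2d(best_x))[0])
    f_val = (eta_pred - window.midpoint) ** 2
    pen = penalty(eta_pred, window, shear_rate=float(best_x[0]), shear_floor=floor)
    return OptResult(
        scenario=scenario,
        optimum={
            "shear_rate": float(best_x[0]), "A": float(best_x[1]),
            "G": float(best_x[2]), "T": float(best_x[3]),
        },
        eta_pred=eta_pred,
        objective=f_val,
        penalty=pen,
        F=f_val + pen,
        in_window=window.contains(eta_pred),
        generations=info["generations"],
        converged=info["converged"],
        best_trace=info["best_trace"],
    )
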