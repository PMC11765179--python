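"""Fitting shear-thinning models to flow curves and thixotropic recovery.

Cross fits minimize squared residuals of log-viscosity — the flow curves
span more than three decades, and raw-space least squares would be
dominated entirely by the zero-shear plateau.  Herschel–Bulkley fits are
done in raw stress space (stress spans about one decade) with the yield
stress bounded at zero.  Adjusted R² is reported on the same scale the
fit was performed on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .datasets import (
    CrossParams,
    HerschelParams,
    InvalidParameterError,
    cross_viscosity,
    herschel_stress,
)

__all__ = [
    "FitResult",
    "ThixotropyTrace",
    "fit_cross",
    "fit_herschel",
    "adjusted_r2",
    "recovery_rate",
    "make_recovery_trace",
]

_FTOL = 1e-10
_MAX_NFEV = 10_000
_N_RESTARTS = 3


@dataclass
class FitResult:
    model: str  # "cross" | "herschel"
    params: CrossParams | HerschelParams
    adj_r2: float
    rss: float
    n_obs: int
    converged: bool
    degenerate: bool = False


@dataclass
class ThixotropyTrace:
    """Three-interval thixotropy (3iTT) time series.

    Intervals follow the standard rest / shear / recovery protocol:
    0–60 s at 1 1/s (at rest), 61–65 s at 100 1/s (structural breakdown,
    emulating nozzle extrusion), 66–185 s at 1 1/s (recovery).
    """

    time: np.ndarray  # s, strictly increasing
    viscosity: np.ndarray  # mPa·s
    intervals: dict = field(
        default_factory=lambda: {"rest": (0.0, 60.0), "shear": (61.0, 65.0), "recovery": (66.0, 185.0)}
    )

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.viscosity = np.asarray(self.viscosity, dtype=float)
        if self.time.shape != self.viscosity.shape:
            raise ValueError("time and viscosity must have the same shape")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("times must be strictly increasing")

    def section(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        if name not in self.intervals:
            raise KeyError(f"missing interval {name!r}")
        lo, hi = self.intervals[name]
        mask = (self.time >= lo) & (self.time <= hi)
        if not mask.any():
            raise ValueError(f"no samples in interval {name!r} [{lo}, {hi}]")
        return self.time[mask], self.viscosity[mask]


def adjusted_r2(observed, predicted, n_params: int) -> float:
    """Adjusted coefficient of determination, 1 - (1-R²)(n-1)/(n-p-1)."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    n = obs.size
    if n <= n_params + 1:
        raise ValueError(f"need more than {n_params + 1} observations, got {n}")
    ss_res = float(np.sum((obs - pred) ** 2))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else -np.inf
    r2 = 1.0 - ss_res / ss_tot
    return 1.0 - (1.0 - r2) * (n - 1) / (n - n_params - 1)


def _as_curve(curve) -> tuple[np.ndarray, np.ndarray]:
    arr = np.asarray(curve, dtype=float)
    if arr.ndim == 2 and arr.shape[1] == 2:
        return arr[:, 0], arr[:, 1]
    raise ValueError("curve must be a sequence of (shear_rate, value) pairs")


def fit_cross(curve) -> FitResult:
    """Least-squares Cross-model fit in log-viscosity space.

    Parameters are optimized as (log eta_inf, log eta_0, log t, m) so the
    positivity constraints hold by construction.  Initialization: eta_0
    from the largest observed viscosity, eta_inf from the smallest, t as
    the reciprocal shear rate at the midpoint of the log-viscosity drop,
    m = 0.8, with up to three jittered restarts on non-convergence.
    """
    gd, eta = _as_curve(curve)
    if gd.size < 6:
        raise ValueError("Cross fit needs at least 6 points")
    if np.any(eta <= 0):
        raise ValueError("viscosities must be positive")
    span = np.log10(gd.max() / gd.min())
    if span < 2:
        raise ValueError("Cross fit needs shear rates spanning >= 2 decades")
    log_eta = np.log(eta)

    if np.ptp(log_eta) < 1e-12:  # no shear thinning at all
        c = float(eta[0])
        params = CrossParams(eta_inf=c * (1 - 1e-9), eta_0=c, t=1.0, m=0.5)
        return FitResult("cross", params, 1.0, 0.0, gd.size, True, degenerate=True)

    eta0_init = float(eta.max())
    etainf_init = float(max(eta.min() * 0.5, 1e-12))
    mid = 0.5 * (log_eta.max() + log_eta.min())
    idx = int(np.argmin(np.abs(log_eta - mid)))
    t_init = 1.0 / float(gd[idx]) if gd[idx] > 0 else 1.0

    def residuals(theta):
        li, l0, lt, m = theta
        ei, e0, t = np.exp(li), np.exp(l0), np.exp(lt)
        model = ei + (e0 - ei) / (1.0 + (t * gd) ** m)
        return np.log(np.maximum(model, 1e-300)) - log_eta

    x0 = np.array([np.log(etainf_init), np.log(eta0_init), np.log(t_init), 0.8])
    lb = np.array([-np.inf, -np.inf, -np.inf, 1e-6])
    ub = np.array([np.inf, np.inf, np.inf, 2.0 - 1e-6])

    best = None
    rng = np.random.default_rng(0)
    for attempt in range(1 + _N_RESTARTS):
        start = x0 if attempt == 0 else x0 + rng.normal(0, 0.3, size=4) * np.array([1, 1, 1, 0.1])
        start = np.clip(start, lb, ub)
        sol = least_squares(
            residuals, start, bounds=(lb, ub), ftol=_FTOL, xtol=_FTOL, gtol=_FTOL,
            max_nfev=_MAX_NFEV,
        )
        if best is None or sol.cost < best.cost:
            best = sol
        if best.cost < 1e-16 or best.status > 0:
            break

    li, l0, lt, m = best.x
    ei, e0 = np.exp(li), np.exp(l0)
    if e0 <= ei:  # degenerate: no resolvable plateau separation
        ei = min(ei, e0 * (1 - 1e-9))
    params = CrossParams(eta_inf=float(ei), eta_0=float(e0), t=float(np.exp(lt)), m=float(m))
    pred = np.log(cross_viscosity(params, gd))
    rss = float(np.sum((pred - log_eta) ** 2))
    return FitResult("cross", params, adjusted_r2(log_eta, pred, 4), rss, gd.size, best.status > 0)


def fit_herschel(curve) -> FitResult:
    """Least-squares Herschel–Bulkley fit in raw stress space.

    Optimizes (tau_0, K, n) with tau_0 >= 0 enforced as a bound.
    Initialization: tau_0 from the smallest stress, n from the slope of
    log(tau - tau_0) against log shear rate, K from the intercept.
    """
    gd, tau = _as_curve(curve)
    if gd.size < 4:
        raise ValueError("Herschel fit needs at least 4 points")
    if np.any(tau <= 0):
        raise ValueError("stresses must be positive")

    tau0_init = max(float(tau.min()) * 0.9, 0.0)
    excess = np.maximum(tau - tau0_init, 1e-12)
    slope, intercept = np.polyfit(np.log(gd), np.log(excess), 1)
    n_init = float(np.clip(slope, 0.05, 1.0))
    k_init = float(np.exp(intercept)) * 1e3  # Pa·s^n -> mPa·s^n

    def residuals(theta):
        t0, k_mpa, n = theta
        return t0 + (k_mpa * 1e-3) * gd ** n - tau

    x0 = np.array([tau0_init, k_init, n_init])
    lb = np.array([0.0, 1e-9, 1e-3])
    ub = np.array([np.inf, np.inf, 1.0])

    best = None
    rng = np.random.default_rng(1)
    for attempt in range(1 + _N_RESTARTS):
        start = x0 if attempt == 0 else x0 * np.exp(rng.normal(0, 0.2, size=3))
        start = np.clip(start, lb, ub)
        sol = least_squares(
            residuals, start, bounds=(lb, ub), ftol=_FTOL, xtol=_FTOL, gtol=_FTOL,
            max_nfev=_MAX_NFEV,
        )
        if best is None or sol.cost < best.cost:
            best = sol
        if best.cost < 1e-18 or best.status > 0:
            break

    t0, k_mpa, n = best.x
    params = HerschelParams(tau_0=float(max(t0, 0.0)), K=float(k_mpa), n=float(min(n, 1.0)))
    pred = herschel_stress(params, gd)
    rss = float(np.sum((pred - tau) ** 2))
    return FitResult("herschel", params, adjusted_r2(tau, pred, 3), rss, gd.size, best.status > 0)


def recovery_rate(
    trace: ThixotropyTrace,
    at_times=(2.0, 20.0, 40.0, 60.0),
    baseline_window: float = 10.0,
) -> dict:
    """Structural recovery after high shear, as percent of the at-rest level.

    For each elapsed time t after the shear interval ends, the rate is
    100 x eta(recovery interval at t) / mean eta over the last
    ``baseline_window`` seconds of the rest interval.  The recovery-phase
    viscosity is linearly interpolated at the requested elapsed times.
    """
    rest_t, rest_eta = trace.section("rest")
    trace.section("shear")  # presence check
    rec_t, rec_eta = trace.section("recovery")

    window_lo = rest_t.max() - baseline_window
    base_mask = rest_t >= window_lo
    baseline = float(rest_eta[base_mask].mean())
    if baseline <= 0:
        raise ValueError("non-positive at-rest baseline viscosity")

    shear_end = trace.intervals["shear"][1]
    rates = {}
    for t in at_times:
        eta_t = float(np.interp(shear_end + t, rec_t, rec_eta))
        rates[float(t)] = 100.0 * eta_t / baseline
    return {
        "rates_percent": rates,
        "baseline_mPas": baseline,
        "definition": (
            f"100 * eta(recovery, t after shear) / mean eta over last "
            f"{baseline_window:g} s of rest interval"
        ),
    }


def make_recovery_trace(
    eta_rest: float,
    eta_sheared: float,
    recovery_fraction: float,
    tau_rec: float,
    dt: float = 0.5,
) -> ThixotropyTrace:
    """Synthetic 3iTT trace with exponential structural recovery.

    The recovery interval follows
    eta(t) = eta_low + (f*eta_rest - eta_low) * (1 - exp(-t/tau_rec)),
    where f is the recovered asymptote as a fraction of the at-rest level
    — a convenient closed form for validating recovery-rate estimates.
    """
    if not (0 < recovery_fraction <= 1.5):
        raise ValueError("recovery_fraction must be in (0, 1.5]")
    t1 = np.arange(0.0, 60.0 + dt / 2, dt)
    t2 = np.arange(61.0, 65.0 + dt / 2, dt)
    t3 = np.arange(66.0, 185.0 + dt / 2, dt)
    eta1 = np.full_like(t1, eta_rest)
    eta2 = np.full_like(t2, eta_sheared)
    elapsed = t3 - 65.0
    asymptote = recovery_fraction * eta_rest
    eta3 = eta_sheared + (asymptote - eta_sheared) * (1.0 - np.exp(-elapsed / tau_rec))
    return ThixotropyTrace(
        np.concatenate([t1, t2, t3]), np.concatenate([eta1, eta2, eta3])
    )
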