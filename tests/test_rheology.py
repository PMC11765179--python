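import numpy as np
import pytest

from bioinkflow.datasets import CANONICAL_SYSTEMS, cross_viscosity, herschel_stress
from bioinkflow.rheology import (
    ThixotropyTrace,
    adjusted_r2,
    fit_cross,
    fit_herschel,
    make_recovery_trace,
    recovery_rate,
)

from conftest import curve_from


class TestAdjustedR2:
    def test_perfect_predictions(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        assert adjusted_r2(y, y, 1) == 1.0

    def test_mean_predictor_is_near_zero(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=500)
        pred = np.full_like(y, y.mean())
        assert adjusted_r2(y, pred, 1) == pytest.approx(0.0, abs=0.01)

    def test_five_point_hand_computed_value(self):
        # RSS = 0.08, TSS = 10, R2 = 0.992, adj = 1 - 0.008*4/2 = 0.984
        obs = [1, 2, 3, 4, 5]
        pred = [1.1, 1.9, 3.2, 3.9, 5.1]
        assert adjusted_r2(obs, pred, 2) == pytest.approx(0.984)

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            adjusted_r2([1, 2, 3], [1, 2, 3], 2)


class TestFitCross:
    @pytest.mark.parametrize("system", CANONICAL_SYSTEMS, ids=lambda s: s[0].label)
    def test_noiseless_parameter_recovery(self, system, noiseless_dataset):
        comp, cross, _ = system
        fit = fit_cross(curve_from(noiseless_dataset, comp.label, "viscosity_mPas"))
        assert fit.converged
        assert fit.params.eta_inf == pytest.approx(cross.eta_inf, rel=1e-3)
        assert fit.params.eta_0 == pytest.approx(cross.eta_0, rel=1e-3)
        assert fit.params.t == pytest.approx(cross.t, rel=1e-3)
        assert fit.params.m == pytest.approx(cross.m, rel=1e-3)

    def test_constant_curve_flagged_degenerate(self):
        gd = np.geomspace(0.1, 100, 10)
        fit = fit_cross(np.column_stack([gd, np.full(10, 500.0)]))
        assert fit.degenerate
        assert fit.params.eta_0 == pytest.approx(500.0)
        assert fit.params.eta_inf == pytest.approx(500.0)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_noisy_fits_keep_high_adjusted_r2(self, seed):
        from bioinkflow.datasets import generate_dataset

        ds = generate_dataset(noise_sigma=0.05, seed=seed)
        for comp, _, _ in CANONICAL_SYSTEMS:
            fit = fit_cross(curve_from(ds, comp.label, "viscosity_mPas"))
            assert fit.adj_r2 >= 0.99

    def test_fitted_curve_is_monotone_decreasing(self, default_dataset):
        fit = fit_cross(curve_from(default_dataset, "A5G2T1", "viscosity_mPas"))
        eta = cross_viscosity(fit.params, np.geomspace(0.1, 100, 200))
        assert np.all(np.diff(eta) < 0)

    def test_insufficient_span_rejected(self):
        gd = np.linspace(1, 5, 8)
        with pytest.raises(ValueError, match="decades"):
            fit_cross(np.column_stack([gd, 1000 / gd]))


class TestFitHerschel:
    @pytest.mark.parametrize("system", CANONICAL_SYSTEMS, ids=lambda s: s[0].label)
    def test_noiseless_parameter_recovery(self, system, noiseless_dataset):
        comp, _, hb = system
        fit = fit_herschel(curve_from(noiseless_dataset, comp.label, "shear_stress_Pa"))
        assert fit.params.tau_0 == pytest.approx(hb.tau_0, rel=5e-3)
        assert fit.params.K == pytest.approx(hb.K, rel=5e-3)
        assert fit.params.n == pytest.approx(hb.n, rel=5e-3)

    def test_pure_power_law_recovers_zero_yield_stress(self):
        gd = np.geomspace(0.1, 100, 15)
        tau = (2000 * 1e-3) * gd**0.4
        fit = fit_herschel(np.column_stack([gd, tau]))
        assert fit.params.tau_0 == pytest.approx(0.0, abs=1e-3)
        assert fit.params.n == pytest.approx(0.4, rel=1e-3)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_herschel([[1.0, 2.0], [2.0, 3.0], [3.0, 4.0]])


class TestRecoveryRate:
    def test_full_recovery_is_100_percent(self):
        trace = make_recovery_trace(1000, 1000, 1.0, 1e-9)
        rates = recovery_rate(trace)["rates_percent"]
        assert all(r == pytest.approx(100.0, rel=1e-6) for r in rates.values())

    def test_half_recovery_is_50_percent(self):
        trace = make_recovery_trace(1000, 500, 0.5, 1e-9)
        rates = recovery_rate(trace)["rates_percent"]
        assert all(r == pytest.approx(50.0, rel=1e-6) for r in rates.values())

    def test_exponential_recovery_matches_closed_form(self):
        eta_rest, eta_low, frac, tau = 1000.0, 100.0, 0.9, 15.0
        trace = make_recovery_trace(eta_rest, eta_low, frac, tau)
        out = recovery_rate(trace, at_times=(2.0, 20.0, 40.0, 60.0))
        for t, rate in out["rates_percent"].items():
            expected = 100.0 * (
                eta_low + (frac * eta_rest - eta_low) * (1 - np.exp(-t / tau))
            ) / eta_rest
            assert rate == pytest.approx(expected, rel=1e-9)

    def test_rates_non_decreasing_for_monotone_recovery(self):
        trace = make_recovery_trace(1000, 100, 0.95, 10.0)
        rates = recovery_rate(trace)["rates_percent"]
        vals = [rates[t] for t in sorted(rates)]
        assert all(a <= b for a, b in zip(vals, vals[1:]))

    def test_missing_interval_rejected(self):
        t = np.arange(0.0, 50.0, 1.0)  # rest interval only
        trace = ThixotropyTrace(t, np.full_like(t, 800.0))
        with pytest.raises(ValueError):
            recovery_rate(trace)
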