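import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bioinkflow.datasets import GridSpec, generate_dataset, CANONICAL_SYSTEMS
from bioinkflow.optimize import (
    OptResult,
    SearchBounds,
    TargetWindow,
    differential_evolution,
    objective,
    optimize_formulation,
    penalty,
)
from bioinkflow.surrogates import fit_tree, log_target

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


class _Const:
    def __init__(self, value):
        self.value = value

    def predict(self, X):
        return np.full(np.atleast_2d(X).shape[0], self.value)


class TestTargetWindow:
    def test_default_midpoint(self):
        w = TargetWindow()
        assert (w.lower, w.upper) == (11.52, 13.12)
        assert w.midpoint == pytest.approx(12.32)

    def test_inverted_window_rejected(self):
        with pytest.raises(ValueError):
            TargetWindow(13.0, 12.0)


class TestObjective:
    def test_midpoint_prediction_scores_zero(self):
        assert objective([1, 2, 3, 4], _Const(12.32)) == 0.0

    def test_unit_deviation_scores_one(self):
        assert objective([1, 2, 3, 4], _Const(13.32)) == pytest.approx(1.0)

    def test_high_shear_deviation_value(self):
        # prediction 9.92 against midpoint 12.32 -> (2.4)^2 = 5.76
        assert objective([60, 5, 3, 1], _Const(9.92)) == pytest.approx(5.76)


class TestPenalty:
    def test_in_window_is_zero(self):
        assert penalty(12.0) == 0.0

    def test_below_window_absolute_deviation(self):
        assert penalty(11.0) == pytest.approx(0.52)

    def test_below_window_signed_variant(self):
        assert penalty(11.0, signed=True) == pytest.approx(-0.52)

    def test_above_window(self):
        assert penalty(13.62) == pytest.approx(0.5)

    def test_shear_floor_quadratic_term(self):
        assert penalty(12.0, shear_rate=40.0, shear_floor=50.0) == pytest.approx(100.0)

    @given(
        eta=st.floats(5.0, 20.0),
        sr=st.floats(0.1, 100.0),
        floor=st.one_of(st.none(), st.floats(10.0, 90.0)),
    )
    def test_non_negative_and_zero_only_when_feasible(self, eta, sr, floor):
        w = TargetWindow()
        p = penalty(eta, w, shear_rate=sr, shear_floor=floor)
        assert p >= 0.0
        feasible = w.contains(eta) and (floor is None or sr > floor)
        if feasible:
            assert p == 0.0
        elif not w.contains(eta):
            assert p > 0.0


class TestDifferentialEvolution:
    def test_1d_quadratic(self):
        x, f, info = differential_evolution(
            lambda X: (np.atleast_2d(X)[:, 0] - 3) ** 2, [[0, 10]], seed=0
        )
        assert x[0] == pytest.approx(3.0, abs=1e-4)

    def test_4d_sphere(self):
        x, f, _ = differential_evolution(
            lambda X: np.sum(np.atleast_2d(X) ** 2, axis=1), [[-5, 5]] * 4, seed=1
        )
        assert f == pytest.approx(0.0, abs=1e-8)

    def test_scalar_objective_supported(self):
        x, f, _ = differential_evolution(
            lambda x: float((x[0] - 1) ** 2 + (x[1] + 2) ** 2), [[-5, 5]] * 2, seed=2
        )
        assert np.allclose(x, [1.0, -2.0], atol=1e-4)

    def test_bit_reproducible_under_fixed_seed(self):
        func = lambda X: np.sum(np.atleast_2d(X) ** 2, axis=1)
        a = differential_evolution(func, [[-2, 2]] * 3, seed=9)
        b = differential_evolution(func, [[-2, 2]] * 3, seed=9)
        assert np.array_equal(a[0], b[0]) and a[1] == b[1]

    def test_best_trace_non_increasing(self):
        _, _, info = differential_evolution(
            lambda X: np.sum(np.atleast_2d(X) ** 4 - np.atleast_2d(X) ** 2, axis=1),
            [[-2, 2]] * 2, seed=3, max_generations=100,
        )
        trace = info["best_trace"]
        assert all(a >= b for a, b in zip(trace, trace[1:]))

    def test_separable_convex_matches_analytic_minimum(self):
        target = np.array([0.5, -1.5, 2.5])
        func = lambda X: np.sum((np.atleast_2d(X) - target) ** 2, axis=1)
        x, _, _ = differential_evolution(func, [[-5, 5]] * 3, seed=4)
        assert np.allclose(x, target, atol=1e-5)

    def test_agrees_with_scipy_on_multimodal_function(self):
        from scipy.optimize import differential_evolution as scipy_de

        def rastrigin(X):
            X = np.atleast_2d(X)
            return np.sum(X**2 - 10 * np.cos(2 * np.pi * X) + 10, axis=1)

        x, f, _ = differential_evolution(rastrigin, [[-4, 4]] * 2, seed=5)
        ref = scipy_de(lambda x: float(rastrigin(x)[0]), [(-4, 4)] * 2, seed=5, tol=1e-10)
        assert f == pytest.approx(ref.fun, abs=1e-6)
        assert f == pytest.approx(0.0, abs=1e-6)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            differential_evolution(lambda X: np.zeros(len(np.atleast_2d(X))), [[1, 1]])
        with pytest.raises(ValueError):
            differential_evolution(
                lambda X: np.zeros(len(np.atleast_2d(X))), [[0, 1]], popsize=3
            )


@pytest.fixture(scope="module")
def small_tree_surrogate():
    # systems 3-5 vary all three composition fractions (T takes 1.0 and 0.5)
    ds = generate_dataset(
        CANONICAL_SYSTEMS[3:6], GridSpec(n=10), noise_sigma=0.0, seed=0
    )
    X, y = log_target(ds)
    return fit_tree(X, y), ds


class TestOptimizeFormulation:
    def test_de_matches_exhaustive_grid_on_tree_surrogate(self, small_tree_surrogate):
        tree, ds = small_tree_surrogate
        bounds = SearchBounds.from_dataset(ds)
        res = optimize_formulation(tree, bounds, "free", seed=0)
        # brute-force lattice over the same box
        arr = bounds.as_array()
        axes = [np.linspace(lo, hi, 25) for lo, hi in arr]
        mesh = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 4)
        preds = tree.predict(mesh)
        w = TargetWindow()
        f = (preds - w.midpoint) ** 2
        pen = np.where(preds < w.lower, w.lower - preds,
                       np.where(preds > w.upper, preds - w.upper, 0.0))
        grid_best = float(np.min(f + pen))
        assert res.F <= grid_best + 1e-9

    def test_constant_midpoint_surrogate_scores_zero(self, default_dataset):
        bounds = SearchBounds.from_dataset(default_dataset)
        res = optimize_formulation(_Const(12.32), bounds, "free", seed=1)
        assert res.F == 0.0
        assert res.in_window

    def test_objective_decomposition_invariants(self, small_tree_surrogate):
        tree, ds = small_tree_surrogate
        res = optimize_formulation(tree, SearchBounds.from_dataset(ds), "free", seed=2)
        assert res.penalty >= 0.0
        assert res.F == pytest.approx(res.objective + res.penalty)
        assert res.F >= res.objective

    def test_highshear_respects_raised_bound(self, small_tree_surrogate):
        tree, ds = small_tree_surrogate
        res = optimize_formulation(tree, SearchBounds.from_dataset(ds), "highshear", seed=3)
        assert res.optimum["shear_rate"] >= 50.0

    def test_optimum_within_bounds(self, small_tree_surrogate):
        tree, ds = small_tree_surrogate
        bounds = SearchBounds.from_dataset(ds)
        res = optimize_formulation(tree, bounds, "free", seed=4)
        for name, (lo, hi) in bounds.as_dict().items():
            assert lo <= res.optimum[name] <= hi

    def test_unknown_scenario_rejected(self, small_tree_surrogate):
        tree, ds = small_tree_surrogate
        with pytest.raises(ValueError):
            optimize_formulation(tree, SearchBounds.from_dataset(ds), "turbo")


class TestSearchBounds:
    def test_from_dataset_observed_ranges(self, default_dataset):
        b = SearchBounds.from_dataset(default_dataset)
        f = default_dataset.frame
        assert b.shear_rate == (f.shear_rate.min(), f.shear_rate.max())
        assert b.A == (2.0, 5.25)
        assert b.T == (0.5, 1.0)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            SearchBounds((1, 1), (0, 1), (0, 1), (0, 1))
        with pytest.raises(ValueError):
            SearchBounds((1, 10), (0, 1), (0, 1), (0, 1), shear_floor=50.0)
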