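import numpy as np
import pytest

from bioinkflow import datasets
from bioinkflow.datasets import (
    CANONICAL_SYSTEMS,
    CompositionSpec,
    CrossParams,
    DatasetFormatError,
    GridSpec,
    HerschelParams,
    InvalidParameterError,
    cross_viscosity,
    generate_dataset,
    herschel_stress,
    read_dataset,
    write_dataset,
)

A5G2T1_CROSS = CrossParams(6191, 4_182_705, 8.05, 0.83)
A5G2T1_HERSCHEL = HerschelParams(255.89, 582.6, 0.22)


class TestCrossViscosity:
    def test_zero_shear_gives_zero_shear_plateau(self):
        assert cross_viscosity(A5G2T1_CROSS, 0.0) == pytest.approx(4_182_705)

    def test_high_shear_approaches_infinite_shear_plateau(self):
        assert cross_viscosity(A5G2T1_CROSS, 1e9) == pytest.approx(6191, rel=1e-3)

    def test_unit_shear_rate_value(self):
        # frozen by direct evaluation of the model with the A5G2T1 row
        assert cross_viscosity(A5G2T1_CROSS, 1.0) == pytest.approx(634530.5338869094)

    @pytest.mark.parametrize("system", CANONICAL_SYSTEMS, ids=lambda s: s[0].label)
    def test_strictly_decreasing_in_shear_rate(self, system):
        _, cross, _ = system
        eta = cross_viscosity(cross, np.geomspace(0.1, 100, 50))
        assert np.all(np.diff(eta) < 0)

    def test_negative_shear_rate_rejected(self):
        with pytest.raises(ValueError):
            cross_viscosity(A5G2T1_CROSS, -1.0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(eta_inf=10, eta_0=5, t=1, m=0.5),  # plateaus inverted
            dict(eta_inf=5, eta_0=10, t=-1, m=0.5),  # non-positive t
            dict(eta_inf=5, eta_0=10, t=1, m=0.0),  # m out of range
            dict(eta_inf=5, eta_0=10, t=1, m=2.5),
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(InvalidParameterError):
            CrossParams(**kwargs)


class TestHerschelStress:
    def test_zero_shear_gives_yield_stress(self):
        assert herschel_stress(A5G2T1_HERSCHEL, 0.0) == pytest.approx(255.89)

    def test_unit_shear_rate_value(self):
        # tau_0 + K*1e-3 with the mPa·s^n -> Pa·s^n conversion
        assert herschel_stress(A5G2T1_HERSCHEL, 1.0) == pytest.approx(256.4726)

    def test_newtonian_reduction(self):
        params = HerschelParams(tau_0=0.0, K=1000.0, n=1.0)
        assert herschel_stress(params, 2.0) == pytest.approx(2.0)

    def test_negative_yield_stress_rejected(self):
        with pytest.raises(InvalidParameterError):
            HerschelParams(tau_0=-1.0, K=100.0, n=0.5)


class TestGenerateDataset:
    def test_zero_noise_reproduces_models_exactly(self, noiseless_dataset):
        for comp, cross, herschel in CANONICAL_SYSTEMS:
            sub = noiseless_dataset.frame[
                noiseless_dataset.frame["composition"] == comp.label
            ]
            gd = sub["shear_rate"].to_numpy()
            assert np.array_equal(
                sub["viscosity_mPas"].to_numpy(), cross_viscosity(cross, gd)
            )
            assert np.array_equal(
                sub["shear_stress_Pa"].to_numpy(), herschel_stress(herschel, gd)
            )

    def test_row_count_is_compositions_times_grid(self, noiseless_dataset):
        assert len(noiseless_dataset) == 8 * 21
        small = generate_dataset(CANONICAL_SYSTEMS[:3], GridSpec(n=10), 0.0, 0)
        assert len(small) == 30

    def test_canonical_total_solids(self):
        for comp, _, _ in CANONICAL_SYSTEMS:
            assert comp.total_solids == 8.0

    def test_deterministic_under_fixed_seed(self):
        a = generate_dataset(noise_sigma=0.05, seed=11)
        b = generate_dataset(noise_sigma=0.05, seed=11)
        assert a.frame.equals(b.frame)
        c = generate_dataset(noise_sigma=0.05, seed=12)
        assert not a.frame.equals(c.frame)

    def test_noise_is_centered_in_log_space(self):
        # Monte-Carlo check of the multiplicative log-normal noise model
        ds = generate_dataset(
            CANONICAL_SYSTEMS[:1], GridSpec(n=2000), noise_sigma=0.05, seed=5
        )
        comp, cross, _ = CANONICAL_SYSTEMS[0]
        gd = ds.frame["shear_rate"].to_numpy()
        log_ratio = np.log(ds.frame["viscosity_mPas"].to_numpy() / cross_viscosity(cross, gd))
        assert abs(log_ratio.mean()) < 4 * 0.05 / np.sqrt(2000)
        assert log_ratio.std() == pytest.approx(0.05, rel=0.15)

    def test_empty_composition_list_rejected(self):
        with pytest.raises(ValueError):
            generate_dataset([], GridSpec(), 0.0, 0)

    def test_grid_outside_instrument_range_rejected(self):
        with pytest.raises(ValueError):
            GridSpec(min=0.01, max=100)
        with pytest.raises(ValueError):
            GridSpec(min=0.1, max=500)

    def test_metadata_records_generation_settings(self):
        ds = generate_dataset(noise_sigma=0.02, seed=9, grid=GridSpec(n=5))
        assert ds.metadata == {
            "seed": 9,
            "noise_sigma": 0.02,
            "grid": {"min": 0.1, "max": 100.0, "n": 5, "spacing": "log"},
        }


class TestCsvRoundTrip:
    def test_write_read_identity(self, tmp_path, noiseless_dataset):
        path = tmp_path / "flow.csv"
        write_dataset(noiseless_dataset, path)
        back = read_dataset(path)
        assert back.frame.columns.tolist() == noiseless_dataset.frame.columns.tolist()
        assert np.allclose(
            back.frame["viscosity_mPas"], noiseless_dataset.frame["viscosity_mPas"],
            rtol=1e-12,
        )
        assert back.metadata == noiseless_dataset.metadata

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("composition,A,G,T,viscosity_mPas,shear_stress_Pa\nx,1,1,6,5,2\n")
        with pytest.raises(DatasetFormatError, match="shear_rate"):
            read_dataset(path)

    def test_reordered_columns_accepted(self, tmp_path):
        path = tmp_path / "reordered.csv"
        path.write_text(
            "shear_rate,composition,A,G,T,shear_stress_Pa,viscosity_mPas\n"
            "1.0,x,1,1,6,2.0,5.0\n"
        )
        ds = read_dataset(path)
        assert ds.frame.loc[0, "viscosity_mPas"] == 5.0

    def test_duplicate_pair_rejected(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text(
            "composition,A,G,T,shear_rate,viscosity_mPas,shear_stress_Pa\n"
            "x,1,1,6,1.0,5.0,2.0\nx,1,1,6,1.0,5.1,2.1\n"
        )
        with pytest.raises(DatasetFormatError, match="duplicate"):
            read_dataset(path)

    def test_non_numeric_cell_rejected(self, tmp_path):
        path = tmp_path / "nan.csv"
        path.write_text(
            "composition,A,G,T,shear_rate,viscosity_mPas,shear_stress_Pa\n"
            "x,1,1,6,1.0,oops,2.0\n"
        )
        with pytest.raises(DatasetFormatError, match="viscosity_mPas"):
            read_dataset(path)


def test_composition_requires_positive_weights():
    with pytest.raises(InvalidParameterError):
        CompositionSpec("bad", 0.0, 5.0, 3.0)
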