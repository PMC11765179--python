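import numpy as np
import pytest

from bioinkflow import datasets
from bioinkflow.surrogates import fit_forest, log_target

DEFAULT_SEED = 42


@pytest.fixture(scope="session")
def noiseless_dataset():
    """All eight canonical compositions, 21-point log grid, zero noise."""
    return datasets.generate_dataset(noise_sigma=0.0, seed=0)


@pytest.fixture(scope="session")
def default_dataset():
    """The default full-scale synthetic dataset (168 rows, sigma = 0.05)."""
    return datasets.generate_dataset(noise_sigma=0.05, seed=DEFAULT_SEED)


@pytest.fixture(scope="session")
def default_Xy(default_dataset):
    return log_target(default_dataset)


@pytest.fixture(scope="session")
def trained_forest(default_Xy):
    """One random forest trained on the full default dataset (shared: slow)."""
    X, y = default_Xy
    return fit_forest(X, y, seed=7)


def curve_from(dataset, label, value_col):
    sub = dataset.frame[dataset.frame["composition"] == label]
    return np.column_stack([sub["shear_rate"].to_numpy(), sub[value_col].to_numpy()])
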