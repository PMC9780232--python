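import numpy as np
import pytest

from scdebench import SimParams, simulate_dataset


@pytest.fixture(scope="session")
def small_params() -> SimParams:
    """Small but realistic dataset: 120 genes, 6+6 individuals, 20 cells each."""
    return SimParams(n_genes=120, prop_de=0.2, n_cases=6, n_controls=6,
                     cells_per_individual_case=20,
                     cells_per_individual_control=20, master_seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_params):
    return simulate_dataset(small_params)


@pytest.fixture(scope="session")
def null_dataset():
    """Null-only data with donor effects: the pseudoreplication stress case."""
    params = SimParams(n_genes=300, prop_de=0.0, n_cases=10, n_controls=10,
                       cells_per_individual_case=50,
                       cells_per_individual_control=50, master_seed=23)
    return simulate_dataset(params)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
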