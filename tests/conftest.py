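import numpy as np
import pytest
from hypothesis import settings

from mlrpower import case_preset, simulate_dataset

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def benchmark_scenario():
    return case_preset("benchmark", "medium")


@pytest.fixture(scope="session")
def toy_dataset(benchmark_scenario):
    """5 clusters x 8 rows, small enough for brute-force integration."""
    rng = np.random.default_rng(12345)
    return simulate_dataset(benchmark_scenario, 8, 5, rng)


@pytest.fixture(scope="session")
def toy_params():
    return dict(
        gamma00=0.1,
        gamma10=0.4,
        gamma01=0.25,
        gamma11=0.2,
        sigma0_sq=1.2,
        sigma1_sq=0.4,
    )
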