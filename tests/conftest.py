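import warnings

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")

from sitransfer.simulate import GeneratorConfig, generate_benchmark

warnings.filterwarnings("ignore", message="reducing output groups")


@pytest.fixture(scope="session")
def benchmarks10():
    """Default synthetic benchmarks for seeds 0..9 (shared across tests)."""
    return [generate_benchmark(GeneratorConfig(seed=s))[0] for s in range(10)]


@pytest.fixture(scope="session")
def benchmark0(benchmarks10):
    return benchmarks10[0]


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
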