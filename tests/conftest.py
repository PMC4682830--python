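import numpy as np
import pytest

from dramote import SamplerConfig, SimSpec, fixture_suite, gaussian_imbalance


@pytest.fixture(scope="session")
def fixtures():
    return fixture_suite()


@pytest.fixture(scope="session")
def imbalanced():
    """Moderate overlapping imbalanced dataset for sampler-law checks."""
    return gaussian_imbalance(
        SimSpec(n_minority=20, n_majority=100, dimension=5, separation=2.0, seed=1)
    )


@pytest.fixture
def sampler_config():
    return SamplerConfig(seed=7)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
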