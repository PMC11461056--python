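import numpy as np
import pytest

from trigom.model_core import PriorConfig, prepare_data
from trigom.inference import SamplerConfig, sample_posterior
from trigom.synthetic import make_fixture


@pytest.fixture(scope="session")
def default32():
    return make_fixture("default32")


@pytest.fixture(scope="session")
def tiny8():
    return make_fixture("tiny8")


@pytest.fixture(scope="session")
def prepared32(default32):
    return prepare_data(default32.abundance, default32.climate)


@pytest.fixture(scope="session")
def prepared8(tiny8):
    return prepare_data(tiny8.abundance, tiny8.climate, anomaly_year=None)


@pytest.fixture(scope="session")
def small_fit(prepared32):
    """A quick shared posterior fit on the 32-year fixture (2 chains, short
    runs): accurate enough for structural/identity checks, not for
    convergence claims."""
    cfg = SamplerConfig(n_chains=2, n_iter=1000, n_burnin=500, thin=5, seed=11)
    return sample_posterior(prepared32, PriorConfig(), cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
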