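import numpy as np
import pytest
from hypothesis import settings

from stepstone.energy import default_matrix
from stepstone.experiment import make_fixtures

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def matrix():
    return default_matrix()


@pytest.fixture(scope="session")
def fixtures():
    return make_fixtures(seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
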