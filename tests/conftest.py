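import numpy as np
import pytest

from synta.dataset import make_fixture, stable_seed
from synta.simulator import SceneConfig, make_sample


@pytest.fixture(scope="session")
def default_config() -> SceneConfig:
    return SceneConfig()


@pytest.fixture(scope="session")
def small_samples(default_config):
    """Ten 256x256 default-config scenes shared across the suite."""
    return [make_sample(default_config, (256, 256), stable_seed(7, i)) for i in range(10)]


@pytest.fixture(scope="session")
def two_fibers():
    return make_fixture("two_fibers")


@pytest.fixture(scope="session")
def single_disk():
    return make_fixture("single_disk")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
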