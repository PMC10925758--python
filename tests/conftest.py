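import numpy as np
import pytest

from volerange import SimConfig, simdata


@pytest.fixture(scope="session")
def default_config() -> SimConfig:
    return SimConfig()


@pytest.fixture(scope="session")
def one_enclosure_config() -> SimConfig:
    return SimConfig(n_enclosures=1, seed=1)


@pytest.fixture(scope="session")
def one_enclosure_dataset(one_enclosure_config):
    """A single simulated enclosure: (agents, fixes, adults, embryos)."""
    return simdata.simulate_dataset(one_enclosure_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)
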