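import numpy as np
import pytest

from babblesim.experiment import RunConfig, run_simulation
from babblesim.network import NetworkConfig, build_network


#: small-but-alive network used by fast unit/smoke tests
SMALL_CONFIG = dict(n_reservoir=200, n_motor=20, fanout=20)


@pytest.fixture(scope="session")
def small_run():
    """A 5-trial run of a scaled-down network (shared across tests)."""
    cfg = RunConfig(seed=3, n_trials=5, **SMALL_CONFIG)
    return run_simulation(cfg)


@pytest.fixture(scope="session")
def default_topology():
    return build_network(seed=0, config=NetworkConfig())


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
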