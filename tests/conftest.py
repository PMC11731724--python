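import numpy as np
import pytest

from cbgtsim.fixtures import make_fixture_network


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_config():
    """Miniature 2-choice configuration (fast, decisions unreliable)."""
    _, config = make_fixture_network(scale="tiny", seed=0)
    return config


@pytest.fixture(scope="session")
def tiny_bundle():
    """One tiny simulation run once per session for structural checks."""
    from cbgtsim.sim import simulate_one

    _, config = make_fixture_network(scale="tiny", seed=3, n_trials=2)
    config["record_variables"] = ["weight", "optogenetic_input"]
    return simulate_one(config)
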