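import numpy as np
import pytest

from normpgg import AgentParams, GameConfig, SimulationConfig, run_experiment


@pytest.fixture(scope="session")
def game_cfg():
    return GameConfig()


@pytest.fixture(scope="session")
def agent_params():
    return AgentParams()


@pytest.fixture(scope="session")
def small_run():
    """A small but non-trivial replicated run shared across tests."""
    cfg = SimulationConfig(replications=3, n_groups=4, master_seed=123)
    return cfg, run_experiment(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(987654321)
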