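import numpy as np
import pytest

from shoalsim.config import default_config
from shoalsim.simulate import AgentState, SimulationConfig, run_simulation


@pytest.fixture(scope="session")
def cfg():
    return default_config()


def make_agent(position=(0.0, 0.0), heading=0.0, length=0.4, height=0.2):
    return AgentState(
        position=np.asarray(position, dtype=float),
        heading=float(heading),
        body_length=length,
        body_height=height,
    )


@pytest.fixture
def agent():
    return make_agent()


@pytest.fixture(scope="session")
def short_run(cfg):
    """A short deterministic 7 dpf non-social run shared across tests."""
    sim = SimulationConfig.from_run_config(cfg, 7, "nonsocial", duration=120.0,
                                           n_agents=3)
    return run_simulation(sim, seed=42)


@pytest.fixture(scope="session")
def ns_runs(cfg):
    """Non-social 7 dpf runs: every non-wall turn is a fair coin."""
    sim = SimulationConfig.from_run_config(cfg, 7, "nonsocial", duration=200.0)
    return [run_simulation(sim, seed=300 + k) for k in range(4)]


@pytest.fixture(scope="session")
def vr7_runs(cfg):
    """A small batch of 7 dpf social runs for inference tests."""
    sim = SimulationConfig.from_run_config(cfg, 7, "vr_social", duration=200.0)
    return [run_simulation(sim, seed=100 + k) for k in range(6)]
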