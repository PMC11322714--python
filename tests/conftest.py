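import numpy as np
import pytest

from walletrdd import SimulationConfig, simulate_panel


@pytest.fixture(scope="session")
def small_sim():
    """One modest simulated cohort shared across read-only tests."""
    cfg = SimulationConfig(n_users=600, seed=42)
    panels, truth = simulate_panel(cfg)
    return cfg, panels, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
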