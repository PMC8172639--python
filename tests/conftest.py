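import numpy as np
import pytest

from brass.simulate import SimulationConfig, simulate_experiment


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Reduced-scale study design: full method/sample grid, fewer cells."""
    return SimulationConfig(cells_flow=1500, cells_microscopy=300, seed=7)


@pytest.fixture(scope="session")
def small_experiment(small_config):
    return simulate_experiment(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
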