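import numpy as np
import pytest

from n2part import SimulationScenario

SEED = 42


@pytest.fixture
def rng():
    return np.random.default_rng(SEED)


@pytest.fixture
def default_scenario():
    """The study design: 4 groups, 5 kill times, triplicates, noise 0.5."""
    return SimulationScenario(seed=SEED)


@pytest.fixture
def quiet_scenario():
    """Same design at low measurement noise, for near-exact recovery."""
    return SimulationScenario(seed=SEED, noise_sd=0.05)


@pytest.fixture
def noiseless_scenario():
    return SimulationScenario(seed=SEED, noise_sd=0.0)
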