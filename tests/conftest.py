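import numpy as np
import pytest

from cse import SimulationConfig, simulate_dataset


@pytest.fixture
def five_obs():
    """Classic textbook sample: times 1..5, the third observation censored."""
    return np.array([1.0, 2.0, 3.0, 4.0, 5.0]), np.array([1, 1, 0, 1, 1])


@pytest.fixture
def small_confounded():
    """One small draw of the confounded synthetic study."""
    return simulate_dataset(SimulationConfig(n_control=250, n_treated=200, seed=42))


@pytest.fixture
def rng():
    return np.random.default_rng(20250920)
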