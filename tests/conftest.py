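import numpy as np
import pytest

from occuhet import ScenarioConfig, simulate_zib_history


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def small_config():
    """Cheap scenario: low density, small movement, few visits."""
    return ScenarioConfig(density=0.1, movement_sd=10.0, psi=0.5,
                          n_sites=40, n_visits=6, seed=7)


@pytest.fixture
def zib_history(rng):
    """Homogeneous zero-inflated binomial history (psi=0.6, p=0.4)."""
    return simulate_zib_history(0.6, 0.4, 300, 10, rng)
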