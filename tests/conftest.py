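import numpy as np
import pytest

from ecosim import Environment, make_equally_spaced_strategies


@pytest.fixture
def env_balanced():
    """Canonical two-nutrient environment: c0 = K = 1, rho0/K = 1e-3."""
    return Environment(c0=1.0, supply_fraction=[0.5, 0.5], K=1.0, rho0=1e-3)


@pytest.fixture
def community21():
    """The canonical 21 equally spaced two-nutrient strategies."""
    return make_equally_spaced_strategies(21)


@pytest.fixture
def equal_inoculum21():
    return np.full(21, 1.0 / 21)
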