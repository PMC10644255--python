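import numpy as np
import pytest

from sterolflux import CONTROL_PARAMS, DISEASE_PARAMS


@pytest.fixture(scope="session")
def disease():
    return DISEASE_PARAMS


@pytest.fixture(scope="session")
def control():
    return CONTROL_PARAMS


@pytest.fixture(scope="session")
def pulse_grid():
    """Pulse-chase sampling grid resolving both kinetic phases (minutes)."""
    return np.linspace(0.0, 360.0, 13)


@pytest.fixture(scope="session")
def dense_pulse_grid():
    """Dense-early pulse-chase design: fast PM/RE/LM cycle plus slow ILV phase."""
    return np.array(
        [0.0, 2, 5, 10, 15, 20, 30, 45, 60, 90, 120, 180, 240, 300, 360, 420, 480]
    )


@pytest.fixture(scope="session")
def rate_rng():
    return np.random.default_rng(20231031)
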