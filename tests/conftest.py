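import numpy as np
import pytest

from synslots import RateConstants


@pytest.fixture
def rates_f07():
    """Standard calibration: F=0.7, phi=2.67, S=188 (Fig. 8 slot set)."""
    return RateConstants.from_targets(0.7, 2.67, 188.0)


@pytest.fixture
def fig8_slots():
    return (1, 2, 5, 10, 20, 50, 100)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
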