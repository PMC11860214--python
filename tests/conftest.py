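import numpy as np
import pytest

from biasloop._rng import spawn_rng
from biasloop.stimuli import build_balanced_set


@pytest.fixture(scope="session")
def balanced_100():
    """100 balanced arrays (50 mirror pairs), fixed seed."""
    return build_balanced_set(50, spawn_rng(1234, "fixtures", "balanced_100"))


@pytest.fixture(scope="session")
def balanced_5000():
    """5,000 balanced arrays for calibration-scale checks."""
    return build_balanced_set(2500, spawn_rng(1234, "fixtures", "balanced_5000"))


@pytest.fixture()
def rng():
    return np.random.default_rng(987)
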