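import numpy as np
import pytest

from suddency import APDParams, ActionPotentialDistribution


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def two_level():
    """Two-level fixture signal: the transform saturates fast, so the APD
    tails vanish well inside the quadrature bracket."""
    return np.array([1.0, 2.0])


@pytest.fixture
def three_signal():
    return np.array([1.0, 2.0, 3.0])


@pytest.fixture
def apd_dist(two_level):
    return ActionPotentialDistribution(two_level, APDParams(0.5, 1.0))
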