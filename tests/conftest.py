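import numpy as np
import pytest

from pathsim import CoreProfile, PathwayAssignment, SimpleModel


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def tiny_simple():
    """Simple model small enough for exhaustive enumeration: P=2, R=3."""
    return SimpleModel(PathwayAssignment.blocks(2, 3), mg=2, mp=1)


@pytest.fixture
def small_profile():
    """Reduced-size core keeping the calibrated load targets."""
    return CoreProfile(n_case=420, n_control=280)


@pytest.fixture
def random_dose_matrix(rng):
    return rng.integers(0, 3, size=(60, 12))
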