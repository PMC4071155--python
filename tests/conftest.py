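import numpy as np
import pytest

from snpvus import MAFProfile, table1_design


@pytest.fixture
def rng():
    return np.random.default_rng(20140614)


@pytest.fixture
def profile_d3():
    """Well-separated 3-class design used across modules."""
    return table1_design(3, 0.1, 60, seed=123)


@pytest.fixture
def identical_profile_d3():
    """Three classes with identical MAFs: a random classifier."""
    theta = np.full((3, 40), 0.3)
    return MAFProfile(theta=theta)
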