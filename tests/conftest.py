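import numpy as np
import pytest

from gtpd import GTPD, gd

# parameter pairs of the five Monte-Carlo benchmark scenarios (GD family)
SCENARIO_PARAMS = [(0.25, 0.5), (0.5, 1.5), (2.5, 0.5), (1.5, 2.5), (2.0, 4.0)]


@pytest.fixture(scope="session")
def scenario_laws():
    return [gd(th, k) for th, k in SCENARIO_PARAMS]


@pytest.fixture(scope="session")
def gd_sample_50():
    """A fixed small GD sample shared by oracle tests."""
    return np.sort(gd(0.5, 1.5).rvs(50, seed=1234))


@pytest.fixture
def rng():
    return np.random.default_rng(20231)
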