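import numpy as np
import pytest

from riskpipe import io
from riskpipe.prs import AncestryGroup
from riskpipe.simulate import simulate_panel


@pytest.fixture(scope="session")
def coeffs():
    return io.load_bcsc_coefficients()


@pytest.fixture(scope="session")
def thresholds():
    return io.load_thresholds()


@pytest.fixture(scope="session")
def panels():
    return simulate_panel(n_snps=120, seed=1)


@pytest.fixture(scope="session")
def white_panel(panels):
    return panels[AncestryGroup.NH_WHITE]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
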