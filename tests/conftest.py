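import numpy as np
import pytest

from adsorbkit import fixtures
from adsorbkit.isec import ColumnVolumes


@pytest.fixture(scope="session")
def calibration():
    """Power-law Stokes calibration fitted to the bundled polystyrene ladder."""
    return fixtures.stokes_calibration()


@pytest.fixture(scope="session")
def cg161c_volumes():
    return ColumnVolumes(v0=1.06, vt=2.30)


@pytest.fixture(scope="session")
def endpoint_series():
    return fixtures.endpoint_series()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
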