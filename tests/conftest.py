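import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from hybridqc.instrument import DEFAULT_TAU_GRID, make_irf
from hybridqc.optics import DCS_GEOMETRY, OpticalProperties


@pytest.fixture(scope="session")
def irf():
    return make_irf()


@pytest.fixture(scope="session")
def tau_grid():
    return DEFAULT_TAU_GRID.copy()


@pytest.fixture(scope="session")
def healthy_props():
    return OpticalProperties(mua=0.1, musp=10.0, wavelength=785.0)


@pytest.fixture(scope="session")
def dcs_geom():
    return DCS_GEOMETRY
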