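import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mevstem import xsec

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")

#: Printed reference table: energy eV -> (theta_el, theta_inel, theta_eff), mrad.
REFERENCE_ANGLES = {
    3e5: (11.84, 0.813, 3.57),
    1e6: (5.24, 0.406, 1.61),
    3e6: (2.14, 0.170, 0.66),
    1e7: (0.70, 0.058, 0.22),
    3e7: (0.24, 0.020, 0.07),
}


@pytest.fixture(scope="session")
def ice():
    return xsec.AMORPHOUS_ICE


@pytest.fixture(scope="session")
def kin_300kev():
    return xsec.kinematics(3e5)


@pytest.fixture(scope="session")
def kin_10mev():
    return xsec.kinematics(1e7)


@pytest.fixture(scope="session")
def model_10mev():
    return xsec.ice_scattering_model(xsec.kinematics(1e7))


@pytest.fixture(scope="session")
def model_300kev():
    return xsec.ice_scattering_model(xsec.kinematics(3e5))


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
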