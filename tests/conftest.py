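import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from ivimr2 import (
    AcquisitionProtocol,
    IvimParameters,
    RelaxometryParameters,
    generate_curve,
)

# Control-group parameter set (pooled non-irradiated lobes): D* = 81.2e-3,
# D = 0.760e-3 mm^2/s, f = 0.276, R2* = 38.42 Hz.
CONTROL_IVIM = IvimParameters(D=0.760e-3, D_star=81.2e-3, f=0.276)
CONTROL_R2STAR = 38.42
F2_IVIM = IvimParameters(D=0.581e-3, D_star=84.4e-3, f=0.241)
F2_R2STAR = 64.34


@pytest.fixture(scope="session")
def protocol() -> AcquisitionProtocol:
    return AcquisitionProtocol.default()


@pytest.fixture(scope="session")
def control_params() -> IvimParameters:
    return CONTROL_IVIM


@pytest.fixture(scope="session")
def control_dwi_curve(protocol):
    return generate_curve(CONTROL_IVIM, protocol)


@pytest.fixture(scope="session")
def control_gre_curve(protocol):
    return generate_curve(RelaxometryParameters(CONTROL_R2STAR), protocol)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260926)
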