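import pytest

from o17mri import AcquisitionProtocol, KineticParams


@pytest.fixture
def protocol_tc3() -> AcquisitionProtocol:
    """Default inhalation protocol with a 3 s circulation delay."""
    return AcquisitionProtocol(tc=3.0)


@pytest.fixture
def protocol_tc0() -> AcquisitionProtocol:
    """Default protocol with immediate tracer availability."""
    return AcquisitionProtocol(tc=0.0)


@pytest.fixture
def ctr_params() -> KineticParams:
    """Control-group three-phase parameters (Tc = 3 s, alpha = 0.7 fit)."""
    return KineticParams(cmro2=2.02, k_g=0.62, k_l=0.39)


@pytest.fixture
def app_params() -> KineticParams:
    """Transgenic-group three-phase parameters (Tc = 3 s, alpha = 0.7 fit)."""
    return KineticParams(cmro2=1.68, k_g=0.45, k_l=0.36)
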