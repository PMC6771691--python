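import numpy as np
import pytest

from bsmap import BSPulse, GAMMA_UT, PhantomSpec, SequenceParams, TissueParams


@pytest.fixture(scope="session")
def fermi_pulse() -> BSPulse:
    """Default mapping pulse: Fermi, 2 ms, 260 deg, +2 kHz."""
    return BSPulse()


@pytest.fixture(scope="session")
def rect_pulse_200hz() -> BSPulse:
    """Rect pulse with gamma*B1/2pi = 200 Hz at 2 kHz offset (closed form)."""
    return BSPulse(shape="rect", duration=2e-3, f_off=2000.0,
                   peak_b1=2 * np.pi * 200 / GAMMA_UT)


@pytest.fixture(scope="session")
def gel() -> TissueParams:
    """Agar-gel QA phantom relaxation times."""
    return TissueParams(t1=0.55, t2=0.07)


@pytest.fixture(scope="session")
def small_phantom_spec() -> PhantomSpec:
    return PhantomSpec(shape=(12, 12, 6))


@pytest.fixture(scope="session")
def default_seq() -> SequenceParams:
    return SequenceParams()
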