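import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from neuroemi.impedance import ComplexImpedance, capacitor_impedance
from neuroemi.interference import shared_cm_impedance
from neuroemi.signal_path import RecordingSetup

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def random_rc_impedance(rng: np.random.Generator, f: float = 50.0) -> ComplexImpedance:
    """Random passive resistive-capacitive impedance (Re ≥ 0, Im ≤ 0)."""
    mag = 10.0 ** rng.uniform(3, 7)
    phase = rng.uniform(-np.pi / 2, 0.0)
    return ComplexImpedance(mag * np.exp(1j * phase), f)


def make_setup(
    z_s: ComplexImpedance,
    z_r: ComplexImpedance,
    z_g: ComplexImpedance,
    z_p_dm: ComplexImpedance,
    z_n_dm: ComplexImpedance,
    z_p_cm: ComplexImpedance | None = None,
    n: int = 1,
) -> RecordingSetup:
    z_p_cm = z_p_cm or z_p_dm
    return RecordingSetup(
        Z_S=z_s, Z_R=z_r, Z_G=z_g,
        Z_OP_P_DM=z_p_dm, Z_OP_N_DM=z_n_dm,
        Z_OP_P_CM=z_p_cm, Z_OP_N_CM=shared_cm_impedance(z_p_cm, n),
        N=n,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def simple_setup():
    """5 kΩ electrodes into a 21 pF (7.58 MΩ at 1 kHz) front end, N = 1."""
    f = 1000.0
    z_in = capacitor_impedance(21e-12, f)
    return make_setup(
        ComplexImpedance(5e3, f), ComplexImpedance(5e3, f), ComplexImpedance(1e3, f),
        z_in, z_in,
    )
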