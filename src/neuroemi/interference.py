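"""Common-mode and differential-mode interference at the amplifier input.

A common-mode voltage at the electrodes reaches each amplifier input through
its own potential divider — the common-mode input impedance against the
electrode path impedance.  If the two dividers are unequal, part of the
common-mode voltage appears *differentially* (the potential-divider effect),
which no amplifier CMRR can remove.  Two matching disciplines make the
dividers equal:

* **rigorous matching** — in an N-channel system sharing one negative input,
  the shared common-mode input impedance is Z_OP_P_CM/N, so the reference
  path impedance must be Z_S/N; the divider difference then cancels exactly
  for any complex Z_S and Z_OP_P_CM.
* **extreme matching** — make both dividers ≈ 1 by keeping every electrode
  impedance negligible next to the common-mode input impedances.  Simple, but
  the full common-mode swing then reaches the front-end, so it must be paired
  with measures that keep that swing small (the saturation warning here).

Differential-mode interference has two parts: true differential pickup at the
electrodes scaled by the signal divider, plus the common-mode-to-differential
conversion above.  The report keeps the two terms separate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

from .coupling import (
    CouplingNetwork,
    ElectrodeEMIEnvironment,
    body_emi,
    cm_dm_decompose,
    electrode_emi_voltages,
    hardware_displacement_current,
)
from .impedance import ComplexImpedance
from .signal_path import RecordingSetup, transfer_factor

__all__ = [
    "MatchingScheme",
    "InterferenceReport",
    "cmi_at_inputs",
    "cmi_differential",
    "shared_cm_impedance",
    "rigorous_match_reference",
    "check_extreme_matching",
    "ExtremeMatchingResult",
    "dmi_differential",
    "interference_pipeline",
]


@dataclass(frozen=True)
class MatchingScheme:
    """Which impedance-matching discipline a setup claims to follow."""

    kind: Literal["rigorous", "extreme"]
    N: int = 1
    tolerance: float = 0.05

    def __post_init__(self) -> None:
        if self.kind not in ("rigorous", "extreme"):
            raise ValueError(f"kind must be 'rigorous' or 'extreme', got {self.kind!r}")
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if self.tolerance < 0:
            raise ValueError("tolerance must be >= 0")


@dataclass(frozen=True)
class InterferenceReport:
    """Amplifier-referred interference phasors with the DM breakdown retained.

    ``dmi_true_dm`` is differential pickup at the electrodes through the
    signal divider; ``dmi_cm_conversion`` is common-mode converted by divider
    imbalance.  They sum to ``V_DMI_OP_DIFF`` exactly.
    """

    frequency: float
    V_EMI_ME_CM: complex
    V_EMI_ME_DM: complex
    V_CMI_OP_P: complex
    V_CMI_OP_N: complex
    V_CMI_OP_DIFF: complex
    dmi_true_dm: complex
    dmi_cm_conversion: complex

    @property
    def V_DMI_OP_DIFF(self) -> complex:
        return self.dmi_true_dm + self.dmi_cm_conversion

    @property
    def divider_imbalance(self) -> complex:
        """CM→DM conversion per volt of common mode (the divider difference)."""
        if self.V_EMI_ME_CM == 0:
            return 0j
        return self.dmi_cm_conversion / self.V_EMI_ME_CM

    @property
    def total_at_amplifier(self) -> complex:
        """V_CMI_OP_DIFF + V_DMI_OP_DIFF — the line amplitude a recording sees."""
        return self.V_CMI_OP_DIFF + self.V_DMI_OP_DIFF


def _dividers(setup: RecordingSetup) -> tuple[complex, complex]:
    zp, zn = setup.Z_OP_P_CM.value, setup.Z_OP_N_CM.value
    zs, zr = setup.Z_S.value, setup.Z_R.value
    return zp / (zp + zs), zn / (zn + zr)


def cmi_at_inputs(v_cm: complex, setup: RecordingSetup) -> tuple[complex, complex]:
    """Common-mode voltage reaching the positive and negative amplifier inputs.

    Each input sees v_cm through its own divider
    Z_OP_CM/(Z_OP_CM + Z_electrode).
    """
    div_p, div_n = _dividers(setup)
    return v_cm * div_p, v_cm * div_n


def cmi_differential(v_cm: complex, setup: RecordingSetup) -> complex:
    """Differential residue of a common-mode voltage: v_cm × (divider_P − divider_N).

    Exactly zero under rigorous matching (Z_R = Z_S/N with Z_OP_N_CM =
    Z_OP_P_CM/N); bounded by the impedance ratio under extreme matching.
    """
    div_p, div_n = _dividers(setup)
    return v_cm * (div_p - div_n)


def shared_cm_impedance(z_p_cm: ComplexImpedance, N: int) -> ComplexImpedance:
    """Common-mode input impedance of the shared negative input: Z_OP_P_CM/N.

    N channels hang their common-mode input impedances in parallel on the one
    shared reference input.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    return z_p_cm.scaled(1.0 / N)


def rigorous_match_reference(z_s: ComplexImpedance, N: int) -> ComplexImpedance:
    """Reference path impedance required by rigorous matching: Z_R = Z_S/N.

    Division by the real channel count preserves phase; e.g. a 6.95×10⁵ Ω
    signal electrode in a 32-channel system wants a 2.17×10⁴ Ω reference bank.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    return z_s.scaled(1.0 / N)


@dataclass(frozen=True)
class ExtremeMatchingResult:
    """Outcome of the extreme-matching predicate with margins."""

    passed: bool
    margin: float  # |Z_OP_N_CM| / (factor·max(|Z_S|,|Z_R|)); >= 1 passes
    residual_cmi_fraction: float  # |divider_P − divider_N|
    cmi_at_positive_input: float  # |V_CMI_OP_P| for the probe common-mode voltage
    saturation_warning: bool


def check_extreme_matching(
    setup: RecordingSetup,
    factor: float = 100.0,
    *,
    v_cm_probe: complex = 1.0,
    input_range_bound: float = float("inf"),
) -> ExtremeMatchingResult:
    """Extreme-matching check: electrode impedances ≪ common-mode input impedance.

    Passes iff max(|Z_S|, |Z_R|) ≤ |Z_OP_N_CM| / factor.  The report carries
    the residual common-mode→differential fraction and flags saturation when
    the common-mode voltage reaching the positive input (for ``v_cm_probe``)
    exceeds ``input_range_bound`` — under extreme matching the common mode
    arrives almost unattenuated.
    """
    if factor <= 0:
        raise ValueError("factor must be > 0")
    z_max = max(abs(setup.Z_S.value), abs(setup.Z_R.value))
    bound = abs(setup.Z_OP_N_CM.value) / factor
    if z_max == 0:
        margin = float("inf")
    else:
        margin = bound / z_max
    div_p, div_n = _dividers(setup)
    v_p, _ = cmi_at_inputs(v_cm_probe, setup)
    return ExtremeMatchingResult(
        passed=z_max <= bound,
        margin=margin,
        residual_cmi_fraction=abs(div_p - div_n),
        cmi_at_positive_input=abs(v_p),
        saturation_warning=abs(v_p) > input_range_bound,
    )


def dmi_differential(
    v_cm: complex, v_dm: complex, setup: RecordingSetup
) -> InterferenceReport:
    """Differential-mode interference at the amplifier, term by term.

    term 1 (true DM pickup):   v_dm × (Z_P+Z_N)/(Z_P+Z_N+Z_S+Z_R)
    term 2 (CM→DM conversion): v_cm × (divider_P − divider_N)

    The divider difference multiplying v_cm is the same imbalance expression
    as in :func:`cmi_differential`, so a pure common-mode input reproduces
    that result.
    """
    term1 = v_dm * transfer_factor(setup)
    term2 = cmi_differential(v_cm, setup)
    v_p, v_n = cmi_at_inputs(v_cm, setup)
    return InterferenceReport(
        frequency=setup.frequency,
        V_EMI_ME_CM=v_cm,
        V_EMI_ME_DM=v_dm,
        V_CMI_OP_P=v_p,
        V_CMI_OP_N=v_n,
        V_CMI_OP_DIFF=v_p - v_n,
        dmi_true_dm=term1,
        dmi_cm_conversion=term2,
    )


def interference_pipeline(
    net: CouplingNetwork,
    env: ElectrodeEMIEnvironment,
    setup: RecordingSetup,
) -> InterferenceReport:
    """Full chain from the mains source to amplifier-referred CMI/DMI phasors.

    body voltage → hardware displacement current → (ground current ≈ hardware
    current, the low-Z_G approximation) → electrode EMI voltages → CM/DM split
    → amplifier dividers.  Linear in V_IE throughout.
    """
    for f in (env.Z_G.frequency, setup.frequency):
        if not math.isclose(f, net.frequency, rel_tol=1e-9):
            raise ValueError(
                f"environment/setup impedances at {f} Hz but interference at "
                f"{net.frequency} Hz"
            )
    v_body = body_emi(net)
    i_d_h = hardware_displacement_current(v_body, net)
    i_gg_star = i_d_h  # ground path carries essentially all hardware current
    v_s, v_r = electrode_emi_voltages(i_gg_star, env)
    v_cm, v_dm = cm_dm_decompose(v_s, v_r)
    return dmi_differential(v_cm, v_dm, setup)
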