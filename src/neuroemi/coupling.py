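"""Capacitive EMI coupling from mains to body to recording hardware.

The mains line is modeled as a phasor source V_IE with internal impedance
Z_IE, coupled to the subject's body (impedance Z_B, body–Earth capacitance
C_BE) either directly through C_IB or, when an electromagnetic shield is
present, through the C_IS → shield → C_SB chain with the shield tied to Earth
through Z_SE.  The recording hardware hangs off the body through the
electrode interface and returns to Earth through its own stray capacitance
C_HE and the lumped impedance Z_IG* between the interference injection point
and the amplifier IC ground.

The displacement current that takes the hardware branch develops voltages
across the ground-electrode path and the inter-electrode tissue impedances;
splitting those voltages into common-mode and differential-mode parts is what
the amplifier ultimately sees.  How the ground-node current divides between
the signal-side and reference-side tissue paths is not observable, so the
split is an explicit input (fractions of the ground current), with a helper
that derives fractions from path admittances when asked.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .impedance import ComplexImpedance

__all__ = [
    "ShieldCoupling",
    "CouplingNetwork",
    "ElectrodeEMIEnvironment",
    "body_emi_unshielded",
    "body_emi_shielded",
    "body_emi",
    "hardware_displacement_current",
    "electrode_emi_voltages",
    "cm_dm_decompose",
    "admittance_split_fractions",
]

#: body impedance band (Ω) that raises no warning: dry-contact to wet-contact
Z_B_TYPICAL = (200.0, 1000.0)


def _cap_z(C: float, omega: float) -> complex:
    return 1.0 / (1j * omega * C)


@dataclass(frozen=True)
class ShieldCoupling:
    """Shield branch elements: source→shield C_IS, shield→body C_SB, shield→Earth Z_SE."""

    C_IS: float
    C_SB: float
    Z_SE: complex

    def __post_init__(self) -> None:
        if self.C_IS <= 0 or self.C_SB <= 0:
            raise ValueError("shield capacitances must be > 0")


@dataclass(frozen=True)
class CouplingNetwork:
    """Mains-to-body-to-hardware coupling elements at one frequency.

    V_IE is the interference source phasor (V), ``frequency`` its frequency in
    Hz.  Z_IG_star lumps the path from the injection point on the brain to the
    recording-system IC ground; C_HE is hardware-to-Earth stray capacitance.
    """

    V_IE: complex
    frequency: float
    Z_IE: complex
    Z_B: complex
    C_BE: float
    C_IB: float
    C_HE: float
    Z_IG_star: complex
    shield: Optional[ShieldCoupling] = None

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise ValueError("interference frequency must be > 0")
        for name in ("C_BE", "C_IB", "C_HE"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        zb = abs(self.Z_B)
        if not (Z_B_TYPICAL[0] <= zb <= Z_B_TYPICAL[1]):
            # outside the dry/wet contact band is legal, just unusual
            import warnings

            warnings.warn(
                f"|Z_B|={zb:.3g} Ω outside the typical {Z_B_TYPICAL} Ω body band",
                stacklevel=3,
            )

    @property
    def omega(self) -> float:
        return 2.0 * math.pi * self.frequency

    def scaled_source(self, k: complex) -> "CouplingNetwork":
        """Same network with V_IE multiplied by *k* (calibration hook)."""
        return CouplingNetwork(
            V_IE=self.V_IE * k,
            frequency=self.frequency,
            Z_IE=self.Z_IE,
            Z_B=self.Z_B,
            C_BE=self.C_BE,
            C_IB=self.C_IB,
            C_HE=self.C_HE,
            Z_IG_star=self.Z_IG_star,
            shield=self.shield,
        )


def _downstream_impedance(net: CouplingNetwork) -> complex:
    """(Z_B + 1/jωC_BE) ∥ (Z_IG* + 1/jωC_HE): body and hardware branches to Earth."""
    w = net.omega
    z_body = net.Z_B + _cap_z(net.C_BE, w)
    z_hw = net.Z_IG_star + _cap_z(net.C_HE, w)
    return z_body * z_hw / (z_body + z_hw)


def body_emi_unshielded(net: CouplingNetwork) -> complex:
    """Interference voltage on the body without shielding (phasor, V).

    Voltage divider of V_IE between the direct-coupling branch
    (Z_IE + 1/jωC_IB) and the grounded body/hardware combination.
    """
    zd = _downstream_impedance(net)
    return net.V_IE * zd / (zd + net.Z_IE + _cap_z(net.C_IB, net.omega))


def body_emi_shielded(net: CouplingNetwork) -> complex:
    """Interference voltage on the body behind an electromagnetic shield.

    Thevenin approximation of the two-stage divider
    source → C_IS → shield (Z_SE to Earth) → C_SB → body::

        V ≈ V_IE · Z_d·Z_SE / [(Z_d + Z_SE + 1/jωC_SB)·(Z_SE + Z_IE + 1/jωC_IS)]

    with Z_d the unshielded downstream impedance.  Direct coupling C_IB is
    disregarded (weak next to the shield path).  A well-grounded shield
    (Z_SE → 0) kills the body voltage; moving the shield closer to the body
    (larger C_SB) raises it.
    """
    if net.shield is None:
        raise ValueError("network has no shield branch; use body_emi_unshielded")
    w = net.omega
    sh = net.shield
    zd = _downstream_impedance(net)
    num = zd * sh.Z_SE
    den = (zd + sh.Z_SE + _cap_z(sh.C_SB, w)) * (sh.Z_SE + net.Z_IE + _cap_z(sh.C_IS, w))
    return net.V_IE * num / den


def body_emi(net: CouplingNetwork) -> complex:
    """Body interference voltage, picking the shielded form when a shield exists."""
    return body_emi_shielded(net) if net.shield is not None else body_emi_unshielded(net)


def body_displacement_current(net: CouplingNetwork) -> complex:
    """Displacement current through the body branch alone (amps, phasor).

    Reported for completeness; the hardware branch current is what reaches
    the electrodes.
    """
    v = body_emi(net)
    return v / (net.Z_B + _cap_z(net.C_BE, net.omega))


def hardware_displacement_current(v_body: complex, net: CouplingNetwork) -> complex:
    """Displacement current through the recording hardware branch (amps).

    I_D_H = V_body / (1/jωC_HE + Z_IG*).
    """
    return v_body / (_cap_z(net.C_HE, net.omega) + net.Z_IG_star)


@dataclass(frozen=True)
class ElectrodeEMIEnvironment:
    """Electrode-side EMI environment: ground path, tissue paths, current split.

    ``f_SG`` and ``f_RG`` are the fractions of the ground-node displacement
    current assigned to the signal-side and reference-side tissue branches
    (I_D_SG = f_SG·I_D_GG*, I_D_RG = f_RG·I_D_GG*).
    """

    Z_G: ComplexImpedance
    Z_SG: ComplexImpedance
    Z_RG: ComplexImpedance
    f_SG: float
    f_RG: float

    def __post_init__(self) -> None:
        if self.f_SG < 0 or self.f_RG < 0 or self.f_SG + self.f_RG > 1.0 + 1e-12:
            raise ValueError(
                f"split fractions must satisfy 0 <= f_SG, f_RG and f_SG+f_RG <= 1 "
                f"(got {self.f_SG}, {self.f_RG})"
            )
        if not self.Z_G.same_frequency(self.Z_SG) or not self.Z_G.same_frequency(self.Z_RG):
            raise ValueError("Z_G, Z_SG, Z_RG must share a frequency")


def admittance_split_fractions(
    z_sg: ComplexImpedance, z_rg: ComplexImpedance, total: float = 1.0
) -> tuple[float, float]:
    """Split fractions inversely proportional to |Z_SG|, |Z_RG|.

    The lower-impedance tissue path carries the larger share.  ``total`` is
    the combined fraction handed to the two branches (≤ 1); the remainder is
    the current returning directly through the ground electrode.
    """
    if not (0.0 <= total <= 1.0):
        raise ValueError("total split fraction must be within [0, 1]")
    g_s, g_r = 1.0 / max(abs(z_sg.value), 1e-300), 1.0 / max(abs(z_rg.value), 1e-300)
    s = g_s + g_r
    return total * g_s / s, total * g_r / s


def ground_path_current_fraction(
    z_g: ComplexImpedance,
    z_s_path: ComplexImpedance,
    z_r_path: ComplexImpedance,
) -> complex:
    """Share of the hardware displacement current returning through the ground path.

    The hardware current reaches IC ground through three parallel routes —
    the signal-electrode path, the reference path and the ground electrode —
    in proportion to their admittances.  A low-impedance ground electrode
    pulls this fraction toward 1, which is what justifies treating the ground
    current as the whole hardware current.
    """
    ys = 1.0 / z_s_path.value
    yr = 1.0 / z_r_path.value
    yg = 1.0 / z_g.value
    return yg / (yg + ys + yr)


def electrode_emi_voltages(
    i_gg_star: complex, env: ElectrodeEMIEnvironment
) -> tuple[complex, complex]:
    """Electrode-referred EMI voltages (vs IC ground) at signal and reference.

    V_EMI_ME_S = I_D_GG*·Z_G + I_D_SG·Z_SG
    V_EMI_ME_R = I_D_GG*·Z_G + I_D_RG·Z_RG
    """
    i_sg = env.f_SG * i_gg_star
    i_rg = env.f_RG * i_gg_star
    v_s = i_gg_star * env.Z_G.value + i_sg * env.Z_SG.value
    v_r = i_gg_star * env.Z_G.value + i_rg * env.Z_RG.value
    return v_s, v_r


def cm_dm_decompose(v_s: complex, v_r: complex) -> tuple[complex, complex]:
    """Common-mode / differential-mode split of a signal–reference voltage pair.

    CM = (v_s + v_r)/2, DM = v_s − v_r; inverse: v_s = CM + DM/2,
    v_r = CM − DM/2.
    """
    return (v_s + v_r) / 2.0, v_s - v_r
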