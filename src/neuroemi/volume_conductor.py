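"""Current-dipole model of extracellular sources in a resistive volume conductor.

A firing neuron is represented as a current dipole: a point current source
(+E, the inactive membrane region) at ``+z_vec`` and a matching sink (−E, the
active region) at ``−z_vec``, carrying extracellular current ``I_EXT`` through
homogeneous isotropic tissue of resistivity ``rho_TIS``.  Superposition of the
two monopole fields gives the current density and potential anywhere outside
the poles.  Grey matter is close to ohmic and isotropic with resistivity
around 1.65–3.9 Ω·m; values outside that band are accepted but warned about.

Electrodes are ideal points: finite site area matters for electrode impedance,
not for pickup geometry.  A three-electrode differential setup carries one
signal site, one reference site and one ground site; the recorded
differential-mode neural signal is V(signal) − V(reference).  Because a
practical reference/ground electrode is much larger than a neuron, spike (AP)
dipoles are assumed visible only at the signal site; slow LFP dipoles are seen
by every site.  That assumption is a toggle, on by default.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

__all__ = [
    "DipoleSource",
    "ElectrodeSite",
    "current_density",
    "dipole_potential",
    "neural_signal_at_electrodes",
]

#: evaluation closer than this to a pole raises rather than clamps (meters)
SINGULARITY_GUARD_M = 0.1e-6

#: cortical grey-matter resistivity band (Ω·m) — warn outside, reject far outside
RHO_TIS_PLAUSIBLE = (0.1, 100.0)
RHO_TIS_TYPICAL = (1.65, 3.9)


@dataclass(frozen=True)
class DipoleSource:
    """Extracellular current dipole.

    Parameters
    ----------
    I_EXT : float
        Extracellular current amplitude in amperes.
    z_vec : tuple/array of 3 floats
        Half-separation vector (meters) from the dipole origin to the current
        source (+E); the sink (−E) sits at ``−z_vec``.
    rho_TIS : float
        Tissue resistivity in Ω·m.
    label : "AP" | "LFP"
        Whether this dipole models a spiking neuron (AP) or a synaptic
        population (LFP).  Controls reference-site visibility in
        :func:`neural_signal_at_electrodes`.
    origin : 3 floats, optional
        Position of the dipole origin in the global frame (meters).
    """

    I_EXT: float
    z_vec: tuple[float, float, float]
    rho_TIS: float
    label: Literal["AP", "LFP"] = "AP"
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        z = np.asarray(self.z_vec, dtype=float)
        if z.shape != (3,):
            raise ValueError("z_vec must be a 3-vector")
        if np.linalg.norm(z) <= 0:
            raise ValueError("dipole half-separation |z_vec| must be > 0")
        if self.label not in ("AP", "LFP"):
            raise ValueError(f"label must be 'AP' or 'LFP', got {self.label!r}")
        lo, hi = RHO_TIS_PLAUSIBLE
        if not (lo <= self.rho_TIS <= hi):
            raise ValueError(
                f"rho_TIS={self.rho_TIS} Ω·m outside accepted range [{lo}, {hi}]"
            )
        tl, th = RHO_TIS_TYPICAL
        if not (tl <= self.rho_TIS <= th):
            warnings.warn(
                f"rho_TIS={self.rho_TIS} Ω·m is outside the typical cortical "
                f"band [{tl}, {th}] Ω·m",
                stacklevel=3,
            )

    @property
    def source_pos(self) -> np.ndarray:
        return np.asarray(self.origin, float) + np.asarray(self.z_vec, float)

    @property
    def sink_pos(self) -> np.ndarray:
        return np.asarray(self.origin, float) - np.asarray(self.z_vec, float)


@dataclass(frozen=True)
class ElectrodeSite:
    """A point electrode with a role in the differential recording chain."""

    site_id: str
    position: tuple[float, float, float]
    role: Literal["signal", "reference", "ground"]

    def __post_init__(self) -> None:
        p = np.asarray(self.position, dtype=float)
        if p.shape != (3,):
            raise ValueError("position must be a 3-vector")
        if self.role not in ("signal", "reference", "ground"):
            raise ValueError(f"unknown role {self.role!r}")


def _pole_vectors(r: np.ndarray, d: DipoleSource) -> tuple[np.ndarray, np.ndarray]:
    r = np.asarray(r, dtype=float)
    if r.shape != (3,):
        raise ValueError("r must be a 3-vector")
    v_src = r - d.source_pos
    v_snk = r - d.sink_pos
    if np.linalg.norm(v_src) < SINGULARITY_GUARD_M or np.linalg.norm(v_snk) < SINGULARITY_GUARD_M:
        raise ValueError(
            f"evaluation point {r} within {SINGULARITY_GUARD_M*1e6:.2g} µm of a dipole pole"
        )
    return v_src, v_snk


def current_density(r, d: DipoleSource) -> np.ndarray:
    """Extracellular current density j(r) of a dipole, in A/m².

    j(r) = (I_EXT/4π)·[(r−z)/|r−z|³ − (r+z)/|r+z|³], the superposition of the
    monopole source at +z and sink at −z.
    """
    v_src, v_snk = _pole_vectors(r, d)
    k = d.I_EXT / (4.0 * math.pi)
    return k * (v_src / np.linalg.norm(v_src) ** 3 - v_snk / np.linalg.norm(v_snk) ** 3)


def dipole_potential(r, d: DipoleSource) -> float:
    """Extracellular potential V(r) of a dipole, in volts.

    V(r) = (I_EXT·ρ_TIS/4π)·[1/|r−z| − 1/|r+z|].  Vanishes on the bisector
    plane and is antisymmetric under source/sink exchange; falls off as 1/r²
    far from the dipole.
    """
    v_src, v_snk = _pole_vectors(r, d)
    k = d.I_EXT * d.rho_TIS / (4.0 * math.pi)
    return k * (1.0 / np.linalg.norm(v_src) - 1.0 / np.linalg.norm(v_snk))


def _sites_by_role(sites: Sequence[ElectrodeSite]) -> dict[str, list[ElectrodeSite]]:
    by_role: dict[str, list[ElectrodeSite]] = {"signal": [], "reference": [], "ground": []}
    for s in sites:
        by_role[s.role].append(s)
    return by_role


def neural_signal_at_electrodes(
    sites: Sequence[ElectrodeSite],
    sources: Iterable[DipoleSource],
    *,
    ap_signal_only: bool = True,
    ap_prefactor: float = 0.5,
) -> tuple[dict[str, float], float]:
    """Per-site potentials and the differential-mode neural signal.

    Returns ``(per_site, v_ns_me_dm)`` where ``per_site`` maps site_id to the
    superposed potential of all sources visible at that site, and
    ``v_ns_me_dm`` is the differential-mode signal delivered to the electrode
    pair::

        V_NS_ME_DM = ap_prefactor · ΣV_AP(signal)
                     + Σ[V_LFP(signal) − V_LFP(reference)]

    With ``ap_signal_only`` (default) AP dipoles contribute only at the signal
    site — the large-reference assumption.  ``ap_prefactor`` scales the AP term
    in the differential combination (default 1/2, the printed form of the
    composed source-to-amplifier expression); set it to 1.0 for plain
    superposition.  Exactly one signal and one reference site are required.
    """
    sources = list(sources)
    by_role = _sites_by_role(sites)
    if len(by_role["signal"]) != 1 or len(by_role["reference"]) != 1:
        raise ValueError(
            "need exactly one signal and one reference site per channel "
            f"(got {len(by_role['signal'])} signal, {len(by_role['reference'])} reference)"
        )
    sig = by_role["signal"][0]
    ref = by_role["reference"][0]

    per_site: dict[str, float] = {}
    for s in sites:
        v = 0.0
        for src in sources:
            if ap_signal_only and src.label == "AP" and s.role != "signal":
                continue
            v += dipole_potential(s.position, src)
        per_site[s.site_id] = v

    v_ap = sum(
        dipole_potential(sig.position, src) for src in sources if src.label == "AP"
    )
    v_lfp_sig = sum(
        dipole_potential(sig.position, src) for src in sources if src.label == "LFP"
    )
    if ap_signal_only:
        v_ap_ref = 0.0
    else:
        v_ap_ref = sum(
            dipole_potential(ref.position, src) for src in sources if src.label == "AP"
        )
    v_lfp_ref = sum(
        dipole_potential(ref.position, src) for src in sources if src.label == "LFP"
    )
    v_dm = ap_prefactor * (v_ap - v_ap_ref) + (v_lfp_sig - v_lfp_ref)
    return per_site, v_dm
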