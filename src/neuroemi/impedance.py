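"""Complex-impedance arithmetic and electrode-interface parameterizations.

All circuit elements in this package are phasor-domain quantities evaluated at
a single stated frequency (mains interference at 50/60 Hz, electrode
characterization at 1 kHz).  An impedance therefore carries its frequency with
it, and combining impedances defined at different frequencies is an error
rather than a silent mistake.  Internal units are SI throughout (Ω, F, Hz).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ComplexImpedance",
    "RandlesParams",
    "capacitor_impedance",
    "resistor_impedance",
    "randles_impedance",
    "parallel",
    "series",
    "frequency_sweep",
    "impedance_from_spec",
]

#: relative tolerance when checking that two impedances share a frequency
_FREQ_RTOL = 1e-9


@dataclass(frozen=True)
class ComplexImpedance:
    """A two-terminal impedance at a single frequency.

    Parameters
    ----------
    value : complex
        Impedance in ohms (phasor convention ``Z = R + jX``).
    frequency : float
        Frequency in Hz at which ``value`` holds.  ``0`` is allowed and means
        DC (useful for resistive elements and the DC limit of a Randles cell);
        negative frequencies are rejected.
    """

    value: complex
    frequency: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.frequency) or self.frequency < 0:
            raise ValueError(f"frequency must be finite and >= 0, got {self.frequency}")
        if not (math.isfinite(self.value.real) and math.isfinite(self.value.imag)):
            raise ValueError(f"impedance value must be finite, got {self.value}")

    @property
    def magnitude(self) -> float:
        return abs(self.value)

    @property
    def phase_deg(self) -> float:
        return math.degrees(math.atan2(self.value.imag, self.value.real))

    def scaled(self, k: float) -> "ComplexImpedance":
        """Impedance multiplied by a real positive factor (frequency kept)."""
        if k < 0:
            raise ValueError("scale factor must be >= 0")
        return ComplexImpedance(self.value * k, self.frequency)

    def same_frequency(self, other: "ComplexImpedance") -> bool:
        f1, f2 = self.frequency, other.frequency
        return math.isclose(f1, f2, rel_tol=_FREQ_RTOL, abs_tol=1e-12)


@dataclass(frozen=True)
class RandlesParams:
    """Textbook Randles cell: R_s in series with (R_ct parallel C_dl).

    R_s is the solution/spreading resistance, R_ct the charge-transfer
    resistance, C_dl the double-layer capacitance of the electrode–electrolyte
    interface.  No Warburg element is included.
    """

    R_s: float
    R_ct: float
    C_dl: float

    def __post_init__(self) -> None:
        for name in ("R_s", "R_ct", "C_dl"):
            v = getattr(self, name)
            if not math.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and > 0, got {v}")


def resistor_impedance(R: float, f: float) -> ComplexImpedance:
    """Ideal resistor: frequency-independent real impedance tagged with *f*."""
    if R < 0:
        raise ValueError(f"resistance must be >= 0, got {R}")
    return ComplexImpedance(complex(R, 0.0), f)


def capacitor_impedance(C: float, f: float) -> ComplexImpedance:
    """Ideal capacitor impedance 1/(j·2π·f·C).

    Magnitude is 1/(2πfC); e.g. a 21 pF amplifier input capacitance presents
    |Z| ≈ 7.6 MΩ at 1 kHz.
    """
    if not math.isfinite(C) or C <= 0:
        raise ValueError(f"capacitance must be finite and > 0, got {C}")
    if not math.isfinite(f) or f <= 0:
        raise ValueError(f"frequency must be finite and > 0, got {f}")
    return ComplexImpedance(1.0 / (1j * 2.0 * math.pi * f * C), f)


def randles_impedance(p: RandlesParams, f: float) -> ComplexImpedance:
    """Randles-cell impedance Z = R_s + R_ct / (1 + j·2π·f·R_ct·C_dl).

    At DC (f = 0) this is R_s + R_ct; as f → ∞ it tends to R_s.  |Z| is
    monotonically non-increasing in frequency.
    """
    if not math.isfinite(f) or f < 0:
        raise ValueError(f"frequency must be finite and >= 0, got {f}")
    z = p.R_s + p.R_ct / (1.0 + 1j * 2.0 * math.pi * f * p.R_ct * p.C_dl)
    return ComplexImpedance(z, f)


def _check_common_frequency(zs: Sequence[ComplexImpedance]) -> float:
    if len(zs) == 0:
        raise ValueError("need at least one impedance")
    f0 = zs[0].frequency
    for z in zs[1:]:
        if not zs[0].same_frequency(z):
            raise ValueError(
                f"impedances defined at different frequencies: {f0} Hz vs {z.frequency} Hz"
            )
    return f0


def parallel(zs: Sequence[ComplexImpedance]) -> ComplexImpedance:
    """Parallel combination 1 / Σ(1/Z_i); all elements at the same frequency.

    Any short (Z = 0) in the list shorts the result.  k identical impedances
    combine to Z/k, which is how a bank of k matched electrodes behaves.
    """
    f0 = _check_common_frequency(zs)
    if any(z.value == 0 for z in zs):
        return ComplexImpedance(0j, f0)
    y = sum(1.0 / z.value for z in zs)
    return ComplexImpedance(1.0 / y, f0)


def series(zs: Sequence[ComplexImpedance]) -> ComplexImpedance:
    """Series combination Σ Z_i; all elements at the same frequency."""
    f0 = _check_common_frequency(zs)
    return ComplexImpedance(sum((z.value for z in zs), 0j), f0)


def frequency_sweep(
    element, freqs: Iterable[float]
) -> "np.ndarray":
    """Evaluate a parameterized element over a frequency grid.

    ``element`` is either a ``RandlesParams`` (evaluated with
    :func:`randles_impedance`) or a capacitance in farads given as a plain
    float (evaluated with :func:`capacitor_impedance`).  Returns a complex
    array of impedance values, one per frequency.
    """
    freqs = np.asarray(list(freqs), dtype=float)
    if isinstance(element, RandlesParams):
        return np.array([randles_impedance(element, f).value for f in freqs])
    C = float(element)
    return np.array([capacitor_impedance(C, f).value for f in freqs])


def impedance_from_spec(spec: dict, default_freq: float | None = None) -> ComplexImpedance:
    """Build an impedance from a config-file entry.

    Two forms are accepted::

        {z_mag: 6.95e5, z_phase_deg: -88, freq: 1000}
        {randles: {R_s: 1e4, R_ct: 5e7, C_dl: 2.29e-10}, freq: 1000}

    ``freq`` may be omitted if *default_freq* is given.
    """
    f = spec.get("freq", default_freq)
    if f is None:
        raise ValueError("impedance spec needs a 'freq' entry or a default frequency")
    f = float(f)
    if "randles" in spec:
        rp = spec["randles"]
        return randles_impedance(
            RandlesParams(float(rp["R_s"]), float(rp["R_ct"]), float(rp["C_dl"])), f
        )
    if "z_mag" in spec:
        mag = float(spec["z_mag"])
        if mag < 0:
            raise ValueError(f"z_mag must be >= 0, got {mag}")
        phase = math.radians(float(spec.get("z_phase_deg", 0.0)))
        return ComplexImpedance(mag * complex(math.cos(phase), math.sin(phase)), f)
    raise ValueError(f"impedance spec must contain 'z_mag' or 'randles': {spec!r}")
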