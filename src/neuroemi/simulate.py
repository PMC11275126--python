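"""Synthetic multichannel recordings and the five-stage interference re-enactment.

A synthetic recording is the exact sum of three ground-truth components:

* **spikes** — biphasic difference-of-Gaussians templates (1.2 ms) placed at
  Poisson times with a refractory period, one train per unit, with per-spike
  peak-to-peak amplitudes drawn around each unit's mean;
* **LFP** — band-limited Gaussian noise (< 300 Hz) at a target rms;
* **interference** — a mains-frequency sinusoid whose amplitude is whatever
  the coupling + interference circuit model delivers to the amplifier input
  for the stage's impedances.

The five-stage experiment walks a sequence of electrode configurations
(reference/ground electrode counts and the resulting parallel impedances),
recomputes the modeled line amplitude per stage, synthesizes a recording for
each, and reports the 50 Hz spectral line and per-unit spike statistics.  The
measured in vivo line densities are used only to set the overall interference
scale (a single calibration factor on the source); the stage-to-stage
*decrease* is the model's own output.

Everything stochastic takes an explicit seed; the same seed reproduces every
sample bit for bit.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from . import constants as C
from .coupling import CouplingNetwork, ElectrodeEMIEnvironment
from .impedance import ComplexImpedance, parallel, resistor_impedance
from .interference import interference_pipeline, shared_cm_impedance
from .signal_path import RecordingSetup

__all__ = [
    "SpikeUnit",
    "StageConfig",
    "Recording",
    "PSDResult",
    "biphasic_template",
    "synthesize_recording",
    "welch_psd",
    "psd_at_line",
    "line_amplitude_from_psd",
    "spike_pp_stats",
    "run_stage_experiment",
    "default_spike_units",
    "default_stage_fixture",
    "default_coupling_network",
    "stage_recording_setup",
    "stage_environment",
    "stage_interference_amplitude",
    "calibrate_source_to_line_psd",
    "amplitude_for_peak_density",
]

LFP_BAND_UPPER_HZ = 300.0
SPIKE_BAND_UPPER_HZ = 10e3
DEFAULT_FS = 32_000.0  # 1.024 MSPS shared across 32 channels
MAINS_HZ = 50.0

#: equivalent noise bandwidth of a Hann window, in bins
HANN_ENBW_BINS = 1.5


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpikeUnit:
    """One spiking unit: mean peak-to-peak amplitude, jitter, and firing rate."""

    name: str
    pp_mean_v: float
    pp_sd_v: float = 0.0
    rate_hz: float = 5.0
    refractory_s: float = 2e-3

    def __post_init__(self) -> None:
        if self.pp_mean_v <= 0 or self.pp_sd_v < 0 or self.rate_hz <= 0:
            raise ValueError("spike unit needs pp_mean_v > 0, pp_sd_v >= 0, rate_hz > 0")


def default_spike_units() -> tuple[SpikeUnit, SpikeUnit]:
    """Two units at the reference-experiment amplitudes (947.55 and 312.32 µVpp)."""
    return (
        SpikeUnit("neuron1", pp_mean_v=947.55e-6, pp_sd_v=62.94e-6),
        SpikeUnit("neuron2", pp_mean_v=312.32e-6, pp_sd_v=49.68e-6),
    )


@dataclass(frozen=True)
class StageConfig:
    """One optimization stage: electrode counts and effective impedances.

    Each impedance is a mapping frequency → :class:`ComplexImpedance` and must
    carry entries at both the mains frequency (50 Hz) and the 1 kHz
    characterization frequency.  ``Z_ref_parallel`` is the reference bank,
    ``Z_gnd_parallel`` the total ground path (skull wire in parallel with any
    added cortical grounds), ``Z_SG_eff``/``Z_RG_eff`` the effective tissue
    impedances from the signal/reference sites to the ground node, and
    ``f_SG``/``f_RG`` the ground-current split fractions.
    """

    stage: int
    description: str
    n_reference: int
    n_ground: int
    Z_ref_parallel: Mapping[float, ComplexImpedance]
    Z_gnd_parallel: Mapping[float, ComplexImpedance]
    Z_SG_eff: Mapping[float, ComplexImpedance]
    Z_RG_eff: Mapping[float, ComplexImpedance]
    f_SG: float = 0.25
    f_RG: float = 0.20

    def __post_init__(self) -> None:
        if self.stage < 1:
            raise ValueError("stage index must be >= 1")
        if self.n_reference < 0 or self.n_ground < 0:
            raise ValueError("electrode counts must be >= 0")
        for name in ("Z_ref_parallel", "Z_gnd_parallel", "Z_SG_eff", "Z_RG_eff"):
            entries = getattr(self, name)
            for f_req in (MAINS_HZ, 1000.0):
                if f_req not in entries:
                    raise ValueError(f"{name} needs an entry at {f_req} Hz")


@dataclass(frozen=True)
class GroundTruth:
    """Per-component traces and spike times backing a synthetic recording."""

    spike_times: Mapping[str, tuple[np.ndarray, ...]]  # unit -> per-channel times (s)
    spike_amplitudes: Mapping[str, tuple[np.ndarray, ...]]
    spikes: np.ndarray  # channels × samples
    lfp: np.ndarray
    interference: np.ndarray
    interference_amplitude_v: float
    interference_freq_hz: float


@dataclass(frozen=True)
class Recording:
    """Seeded multichannel time series with full ground truth."""

    samples: np.ndarray  # channels × samples, volts
    fs: float
    seed: int
    ground_truth: GroundTruth

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.samples.shape[1] / self.fs

    def times(self) -> np.ndarray:
        return np.arange(self.samples.shape[1]) / self.fs

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.samples.T, columns=[f"ch{i}" for i in range(self.n_channels)]
        )
        df.insert(0, "t_s", self.times())
        return df

    def save_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def save_binary(self, path_prefix) -> None:
        """Raw float64 little-endian samples plus a JSON sidecar."""
        raw = f"{path_prefix}.bin"
        self.samples.astype("<f8").tofile(raw)
        sidecar = {
            "channels": self.n_channels,
            "samples_per_channel": int(self.samples.shape[1]),
            "fs_hz": self.fs,
            "dtype": "<f8",
            "units": "V",
            "layout": "channel-major",
            "seed": self.seed,
            "interference_amplitude_v": self.ground_truth.interference_amplitude_v,
            "interference_freq_hz": self.ground_truth.interference_freq_hz,
        }
        with open(f"{path_prefix}.json", "w") as fh:
            json.dump(sidecar, fh, indent=2)


@dataclass(frozen=True)
class PSDResult:
    """One-sided Welch density with the estimation parameters that produced it."""

    frequencies: np.ndarray
    density: np.ndarray  # V²/Hz
    fs: float
    window: str
    nperseg: int
    noverlap: int
    parseval_ratio: float  # ∫PSD df / mean(x²); ≈ 1 for a good estimate

    def __post_init__(self) -> None:
        if np.any(self.density < 0):
            raise ValueError("density must be non-negative")
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequency grid must be strictly increasing")


# ---------------------------------------------------------------------------
# waveform building blocks
# ---------------------------------------------------------------------------

def biphasic_template(fs: float, duration_s: float = 1.2e-3) -> np.ndarray:
    """Biphasic spike template (difference of Gaussians), unit peak-to-peak.

    A narrow negative lobe followed by a broader positive lobe, the classic
    extracellular spike shape.  Normalized so max − min = 1.
    """
    n = max(int(round(duration_s * fs)), 8)
    t = (np.arange(n) - n / 2.0) / fs
    s1 = duration_s / 8.0
    s2 = duration_s / 4.0
    w = -np.exp(-0.5 * (t / s1) ** 2) + 0.55 * np.exp(-0.5 * ((t - duration_s / 6.0) / s2) ** 2)
    w -= w.mean()
    return w / (w.max() - w.min())


def _poisson_times(
    rng: np.random.Generator, rate_hz: float, refractory_s: float, duration_s: float
) -> np.ndarray:
    """Poisson arrivals with a dead time, over (0, duration)."""
    times = []
    t = 0.0
    while True:
        t += rng.exponential(1.0 / rate_hz) + refractory_s
        if t >= duration_s:
            break
        times.append(t)
    return np.asarray(times)


def _lfp_noise(
    rng: np.random.Generator, n: int, fs: float, rms_v: float, band_upper_hz: float
) -> np.ndarray:
    white = rng.standard_normal(n)
    sos = sps.butter(4, band_upper_hz, btype="low", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, white)
    r = np.sqrt(np.mean(x**2))
    return x * (rms_v / r) if r > 0 else x


# ---------------------------------------------------------------------------
# stage → circuit model
# ---------------------------------------------------------------------------

def _capacitive(mag_1khz: float, f: float) -> ComplexImpedance:
    """Purely capacitive electrode impedance scaled from its 1 kHz magnitude."""
    return ComplexImpedance(-1j * mag_1khz * 1000.0 / f, f)


def stage_recording_setup(
    stage: StageConfig,
    frequency: float = MAINS_HZ,
    *,
    z_signal_1khz: float = C.SIGNAL_ELECTRODE_IMPEDANCE_1KHZ_OHM,
    opa_capacitance_f: float = C.OPA_INPUT_CAPACITANCE_F,
    n_channels: int = C.REFERENCE_CHANNEL_COUNT,
) -> RecordingSetup:
    """Recording setup for a stage at the given frequency.

    The signal electrode and the amplifier input are capacitive (scaled from
    their 1 kHz magnitudes); the reference and ground paths come from the
    stage fixture.  The shared negative input sees 1/N of the per-channel
    common-mode input impedance.
    """
    z_op = ComplexImpedance(
        1.0 / (1j * 2 * math.pi * frequency * opa_capacitance_f), frequency
    )
    return RecordingSetup(
        Z_S=_capacitive(z_signal_1khz, frequency),
        Z_R=stage.Z_ref_parallel[frequency],
        Z_G=stage.Z_gnd_parallel[frequency],
        Z_OP_P_DM=z_op,
        Z_OP_N_DM=z_op,
        Z_OP_P_CM=z_op,
        Z_OP_N_CM=shared_cm_impedance(z_op, n_channels),
        N=n_channels,
    )


def stage_environment(
    stage: StageConfig, frequency: float = MAINS_HZ
) -> ElectrodeEMIEnvironment:
    """Electrode-side EMI environment (ground path, tissue paths, splits) for a stage."""
    return ElectrodeEMIEnvironment(
        Z_G=stage.Z_gnd_parallel[frequency],
        Z_SG=stage.Z_SG_eff[frequency],
        Z_RG=stage.Z_RG_eff[frequency],
        f_SG=stage.f_SG,
        f_RG=stage.f_RG,
    )


def stage_interference_amplitude(
    stage: StageConfig, net: CouplingNetwork, **setup_kwargs
) -> float:
    """Modeled mains-line amplitude (V) at the amplifier input for one stage.

    |V_CMI_OP_DIFF + V_DMI_OP_DIFF| from the full interference pipeline run on
    the stage's impedances at the interference frequency.
    """
    setup = stage_recording_setup(stage, net.frequency, **setup_kwargs)
    env = stage_environment(stage, net.frequency)
    report = interference_pipeline(net, env, setup)
    return abs(report.total_at_amplifier)


# ---------------------------------------------------------------------------
# synthesis and analysis
# ---------------------------------------------------------------------------

def synthesize_recording(
    stage: Optional[StageConfig],
    net: Optional[CouplingNetwork],
    duration_s: float,
    fs: float = DEFAULT_FS,
    seed: int = 0,
    *,
    units: Sequence[SpikeUnit] | None = None,
    n_channels: int = 1,
    lfp_rms_v: float = 100e-6,
    interference_amplitude_v: Optional[float] = None,
    interference_freq_hz: float = MAINS_HZ,
    spike_band_upper_hz: float = SPIKE_BAND_UPPER_HZ,
) -> Recording:
    """Seeded synthetic recording: spikes + LFP + modeled mains interference.

    The interference amplitude is taken from the circuit model
    (:func:`stage_interference_amplitude` on ``stage``/``net``) unless
    ``interference_amplitude_v`` overrides it; with neither, no line is
    injected.  The three components are stored separately and sum to the
    composite exactly.  Identical seeds give bit-identical output.
    """
    if duration_s <= 0:
        raise ValueError("duration must be > 0")
    if fs < 2000.0:
        raise ValueError(f"fs must be at least 2 kHz, got {fs}")
    if fs < 2.0 * spike_band_upper_hz:
        raise ValueError(
            f"fs = {fs} Hz is below twice the spike-band upper edge "
            f"({spike_band_upper_hz} Hz)"
        )
    if units is None:
        units = default_spike_units()

    if interference_amplitude_v is None:
        if stage is not None and net is not None:
            interference_amplitude_v = stage_interference_amplitude(stage, net)
        else:
            interference_amplitude_v = 0.0

    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    template = biphasic_template(fs)
    tlen = len(template)

    spikes = np.zeros((n_channels, n))
    lfp = np.zeros((n_channels, n))
    interference = np.zeros((n_channels, n))
    t = np.arange(n) / fs

    spike_times: dict[str, list[np.ndarray]] = {u.name: [] for u in units}
    spike_amps: dict[str, list[np.ndarray]] = {u.name: [] for u in units}

    for ch in range(n_channels):
        for u in units:
            times = _poisson_times(rng, u.rate_hz, u.refractory_s, duration_s)
            amps = np.maximum(
                rng.normal(u.pp_mean_v, u.pp_sd_v, size=times.size), 0.05 * u.pp_mean_v
            )
            kept_t, kept_a = [], []
            for ti, ai in zip(times, amps):
                i0 = int(round(ti * fs))
                if i0 + tlen >= n:
                    continue
                spikes[ch, i0 : i0 + tlen] += ai * template
                kept_t.append(ti)
                kept_a.append(ai)
            spike_times[u.name].append(np.asarray(kept_t))
            spike_amps[u.name].append(np.asarray(kept_a))
        lfp[ch] = _lfp_noise(rng, n, fs, lfp_rms_v, LFP_BAND_UPPER_HZ)
        phase = rng.uniform(0.0, 2.0 * math.pi)
        interference[ch] = interference_amplitude_v * np.sin(
            2.0 * math.pi * interference_freq_hz * t + phase
        )

    gt = GroundTruth(
        spike_times={k: tuple(v) for k, v in spike_times.items()},
        spike_amplitudes={k: tuple(v) for k, v in spike_amps.items()},
        spikes=spikes,
        lfp=lfp,
        interference=interference,
        interference_amplitude_v=float(interference_amplitude_v),
        interference_freq_hz=interference_freq_hz,
    )
    return Recording(samples=spikes + lfp + interference, fs=fs, seed=seed, ground_truth=gt)


def welch_psd(
    rec: Recording | np.ndarray,
    channel: int = 0,
    *,
    fs: Optional[float] = None,
    segment_s: float = 1.0,
) -> PSDResult:
    """One-sided Welch density: Hann window, 1 s segments, 50% overlap.

    Accepts a :class:`Recording` (picking ``channel``) or a bare 1-D array
    with ``fs``.  The Parseval ratio (integrated density over signal power) is
    recorded alongside the estimate.
    """
    if isinstance(rec, Recording):
        x = rec.samples[channel]
        fs = rec.fs
    else:
        if fs is None:
            raise ValueError("fs is required for a bare array")
        x = np.asarray(rec, dtype=float)
    nperseg = min(int(round(segment_s * fs)), x.size)
    noverlap = nperseg // 2
    f, pxx = sps.welch(
        x, fs=fs, window="hann", nperseg=nperseg, noverlap=noverlap,
        detrend="constant", scaling="density",
    )
    power = float(np.mean((x - x.mean()) ** 2))
    integral = float(np.trapezoid(pxx, f))
    ratio = integral / power if power > 0 else 1.0
    return PSDResult(
        frequencies=f, density=pxx, fs=float(fs), window="hann",
        nperseg=nperseg, noverlap=noverlap, parseval_ratio=ratio,
    )


def psd_at_line(psd: PSDResult, f0: float, halfwidth_hz: float = 1.0) -> float:
    """Peak density (V²/Hz) within ±halfwidth of the line frequency f0."""
    mask = np.abs(psd.frequencies - f0) <= halfwidth_hz
    if not mask.any():
        raise ValueError(f"no frequency bins within ±{halfwidth_hz} Hz of {f0} Hz")
    return float(psd.density[mask].max())


def line_amplitude_from_psd(psd: PSDResult, f0: float, halfwidth_hz: float = 2.0) -> float:
    """Sinusoid amplitude recovered from integrated line power: A = √(2·∫P df)."""
    mask = np.abs(psd.frequencies - f0) <= halfwidth_hz
    df = psd.frequencies[1] - psd.frequencies[0]
    p = float(psd.density[mask].sum() * df)
    return math.sqrt(2.0 * p)


def amplitude_for_peak_density(peak_density: float, df_hz: float = 1.0) -> float:
    """Sinusoid amplitude whose Welch peak density (Hann, on-bin) equals the target.

    Peak density ≈ (A²/2) / ENBW with ENBW = 1.5·df for a Hann window.
    """
    return math.sqrt(2.0 * HANN_ENBW_BINS * df_hz * peak_density)


def spike_pp_stats(
    rec: Recording,
    channel: int = 0,
    *,
    window_s: float = 2e-3,
    highpass_hz: Optional[float] = None,
) -> pd.DataFrame:
    """Per-unit mean and sd of spike peak-to-peak amplitude (µV).

    Spikes are located by their ground-truth times (no sorting); peak-to-peak
    is max − min of the trace within ±``window_s`` of each spike.  With
    ``highpass_hz`` set, the composite is high-pass filtered first
    (4th-order Butterworth, zero phase), the standard spike-band treatment
    that removes LFP and mains content before measuring amplitudes.
    """
    x = rec.samples[channel]
    if highpass_hz is not None:
        sos = sps.butter(4, highpass_hz, btype="high", fs=rec.fs, output="sos")
        x = sps.sosfiltfilt(sos, x)
    half = int(round(window_s * rec.fs))
    rows = []
    for unit, per_ch in rec.ground_truth.spike_times.items():
        times = per_ch[channel]
        pps = []
        for ti in times:
            # template insertion starts at the spike time; center the window there
            i0 = int(round(ti * rec.fs)) + half // 2
            lo, hi = max(i0 - half, 0), min(i0 + half, x.size)
            if hi - lo < 2:
                continue
            seg = x[lo:hi]
            pps.append(seg.max() - seg.min())
        pps = np.asarray(pps)
        rows.append(
            {
                "unit": unit,
                "n_spikes": int(pps.size),
                "pp_mean_uv": float(pps.mean() * 1e6) if pps.size else np.nan,
                "pp_sd_uv": float(pps.std(ddof=1) * 1e6) if pps.size > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)


def run_stage_experiment(
    stages: Sequence[StageConfig],
    net: CouplingNetwork,
    seed: int = 0,
    *,
    duration_s: float = 8.0,
    fs: float = DEFAULT_FS,
    units: Sequence[SpikeUnit] | None = None,
    lfp_rms_v: float = 100e-6,
    spike_highpass_hz: float = 300.0,
) -> pd.DataFrame:
    """Synthesize and analyze one recording per stage; one table row per stage.

    Every stage reuses the same seed, so the spike trains and LFP are
    identical across stages and only the modeled interference changes — the
    analogue of watching the same cortex through successive electrode
    configurations.  Columns: modeled line amplitude, measured 50 Hz Welch
    density, and per-unit spike peak-to-peak statistics (spike band,
    high-passed at ``spike_highpass_hz``).
    """
    if units is None:
        units = default_spike_units()
    rows = []
    for stage in stages:
        amp = stage_interference_amplitude(stage, net)
        rec = synthesize_recording(
            stage, net, duration_s, fs, seed, units=units, lfp_rms_v=lfp_rms_v,
            interference_amplitude_v=amp, interference_freq_hz=net.frequency,
        )
        psd = welch_psd(rec)
        row: dict = {
            "stage": stage.stage,
            "description": stage.description,
            "model_line_amplitude_v": amp,
            "line_psd_v2_per_hz": psd_at_line(psd, net.frequency),
        }
        stats = spike_pp_stats(rec, highpass_hz=spike_highpass_hz)
        for _, r in stats.iterrows():
            row[f"{r['unit']}_pp_mean_uv"] = r["pp_mean_uv"]
            row[f"{r['unit']}_pp_sd_uv"] = r["pp_sd_uv"]
            row[f"{r['unit']}_n_spikes"] = r["n_spikes"]
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# reference-experiment fixtures
# ---------------------------------------------------------------------------

def _both_freqs_cap(mag_1khz: float) -> dict[float, ComplexImpedance]:
    return {MAINS_HZ: _capacitive(mag_1khz, MAINS_HZ), 1000.0: _capacitive(mag_1khz, 1000.0)}


def _both_freqs_res(r_ohm: float) -> dict[float, ComplexImpedance]:
    return {MAINS_HZ: resistor_impedance(r_ohm, MAINS_HZ), 1000.0: resistor_impedance(r_ohm, 1000.0)}


def _ground_path(skull_ohm: float, added_1khz: Sequence[float]) -> dict[float, ComplexImpedance]:
    out = {}
    for f in (MAINS_HZ, 1000.0):
        elems = [resistor_impedance(skull_ohm, f)] + [_capacitive(m, f) for m in added_1khz]
        out[f] = parallel(elems)
    return out


def default_stage_fixture(skull_ground_ohm: float = 5e3) -> list[StageConfig]:
    """The five-stage electrode-configuration sequence of the reference experiment.

    Reference/ground parallel impedances are the measured 1 kHz values
    (capacitively rescaled to 50 Hz); the skull ground is a kiloohm-range
    resistance.  The effective tissue impedances Z_SG/Z_RG are fixture
    choices: tens of kΩ initially, shrinking as cortical ground electrodes
    are added and the layout is staggered, nearly equal by stage 5.
    """
    zs = C.SIGNAL_ELECTRODE_IMPEDANCE_1KHZ_OHM
    f2 = C.STAGE_FIXTURE_1KHZ
    return [
        StageConfig(
            stage=1,
            description="negative input and ground tied to skull ground",
            n_reference=0, n_ground=0,
            Z_ref_parallel=_both_freqs_res(skull_ground_ohm),
            Z_gnd_parallel=_both_freqs_res(skull_ground_ohm),
            Z_SG_eff=_both_freqs_res(80e3),
            Z_RG_eff=_both_freqs_res(1e3),
        ),
        StageConfig(
            stage=2,
            description="4 reference electrodes; 8 cortical grounds added",
            n_reference=4, n_ground=8,
            Z_ref_parallel=_both_freqs_cap(f2[2]["Z_ref_parallel"]),
            Z_gnd_parallel=_ground_path(skull_ground_ohm, [f2[2]["Z_gnd_added"]]),
            Z_SG_eff=_both_freqs_res(40e3),
            Z_RG_eff=_both_freqs_res(50e3),
        ),
        StageConfig(
            stage=3,
            description="14 reference electrodes: 1:32 match to the signal electrode",
            n_reference=14, n_ground=8,
            Z_ref_parallel=_both_freqs_cap(f2[3]["Z_ref_parallel"]),
            Z_gnd_parallel=_ground_path(skull_ground_ohm, [f2[3]["Z_gnd_added"]]),
            Z_SG_eff=_both_freqs_res(40e3),
            Z_RG_eff=_both_freqs_res(60e3),
        ),
        StageConfig(
            stage=4,
            description="8 more cortical grounds (16 total)",
            n_reference=14, n_ground=16,
            Z_ref_parallel=_both_freqs_cap(f2[4]["Z_ref_parallel"]),
            Z_gnd_parallel=_ground_path(
                skull_ground_ohm, [f2[3]["Z_gnd_added"], f2[4]["Z_gnd_added"]]
            ),
            Z_SG_eff=_both_freqs_res(20e3),
            Z_RG_eff=_both_freqs_res(30e3),
        ),
        StageConfig(
            stage=5,
            description="22 cortical grounds, staggered layout",
            n_reference=14, n_ground=22,
            Z_ref_parallel=_both_freqs_cap(f2[5]["Z_ref_parallel"]),
            Z_gnd_parallel=_ground_path(skull_ground_ohm, [f2[5]["Z_gnd_added"]]),
            Z_SG_eff=_both_freqs_res(4e3),
            Z_RG_eff=_both_freqs_res(4.5e3),
        ),
    ]


def default_coupling_network(frequency: float = MAINS_HZ) -> CouplingNetwork:
    """A plausible unshielded mains coupling fixture (230 V line, pF-scale coupling)."""
    return CouplingNetwork(
        V_IE=230.0,
        frequency=frequency,
        Z_IE=1e6,
        Z_B=500.0,
        C_BE=100e-12,
        C_IB=1e-12,
        C_HE=10e-12,
        Z_IG_star=10e3,
    )


def calibrate_source_to_line_psd(
    stages: Sequence[StageConfig],
    net: CouplingNetwork,
    target_peak_density: float = C.STAGE_LINE_PSD_V2_PER_HZ[1],
    *,
    df_hz: float = 1.0,
) -> CouplingNetwork:
    """Scale the interference source so stage 1 hits a target 50 Hz Welch density.

    The whole pipeline is linear in V_IE, so a single real factor anchors the
    re-enactment's absolute scale to the measured stage-1 line; every later
    stage then follows from the circuit model alone.
    """
    a_target = amplitude_for_peak_density(target_peak_density, df_hz)
    a_model = stage_interference_amplitude(stages[0], net)
    if a_model <= 0:
        raise ValueError("stage-1 model amplitude is zero; cannot calibrate")
    return net.scaled_source(a_target / a_model)
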