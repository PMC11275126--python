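# Methods

## Model overview

Everything in this package is single-frequency phasor circuit algebra plus a
quasi-static volume-conductor field model. The assumptions, in order of
importance:

* **Lumped elements.** Electrodes, tissue paths, amplifier inputs and stray
  couplings are two-terminal complex impedances at one stated frequency.
  Multi-tone interference is a superposition of independent single-frequency
  networks. Each `ComplexImpedance` carries its frequency, and combining
  elements defined at different frequencies is an error, not a silent cast.
* **Homogeneous isotropic tissue.** The dipole field model assumes constant
  resistivity ρ around the electrodes. Grey matter is close to this
  (1.65–3.9 Ω·m, ohmic, isotropic); anisotropic white matter is out of scope.
  Sources accept ρ anywhere in 0.1–100 Ω·m but warn outside the grey-matter
  band.
* **Point electrodes.** Site area matters for impedance, not pickup geometry.
  A consequence used throughout: spike (AP) dipoles are visible only at the
  small signal site, while the large reference/ground electrodes average them
  away and see only LFP. That is a toggle (`ap_signal_only`, default on).
* **Linear amplifier front end.** The amplifier contributes only its input
  impedances (differential-mode and common-mode treated as independent
  inputs, no derivation between them is attempted). Gain stages, noise, and
  saturation dynamics are out of scope; the extreme-matching checker emits a
  threshold warning when the common-mode swing at an input exceeds a
  configurable range bound, nothing more.

## Signal path

The three-electrode loop system for a differential drive V (signal electrode
loop and reference loop sharing ground path Z_G, with the source split
symmetrically ±V/2) is solved two ways: the closed form

    I_S = [Z_G·V + (Z_R+Z_N)·V/2] / D
    I_R = −[Z_G·V + (Z_S+Z_P)·V/2] / D
    D   = (Z_S+Z_P)·Z_G + (Z_R+Z_N)·(Z_S+Z_P+Z_G)

and a generic 2×2 linear solve; tests require agreement to 1e-10 relative,
which guards against sign-convention slips. The sign of the (Z_S+Z_P)·V/2
term in I_R is fixed by requiring I_S + I_R = 0 under full symmetry (the
ground electrode carries no differential current), which the matrix solve
confirms.

The amplifier-input divider form

    V_OP_DIFF = V · (Z_P+Z_N)/(Z_P+Z_N+Z_S+Z_R)

is an exact reduction of the loop system only on the balanced manifold
Z_S + Z_P = Z_R + Z_N (verified symbolically); off that manifold it is the
large-input-impedance approximation, accurate to better than 0.1% once the
input impedances dominate the electrode impedances by ~1e4 — the regime any
usable front end operates in. Tests check exact route equivalence on balanced
draws and the approximation bound on unbalanced ones. The multi-channel case
reuses the single-channel signal path per channel; channel count enters the
model only through the shared common-mode input impedance Z_P_CM/N.

## Interference path

The mains source (V_IE behind Z_IE) drives the body node through C_IB, or —
shielded — through the C_IS → shield → C_SB chain with the shield tied to
Earth through Z_SE; the shielded form is the standard Thevenin approximation
(valid for a well-grounded, low-Z_SE shield), and direct coupling C_IB is
dropped under a shield as negligible next to the shield path. The hardware
branch current I_D_H = V_body/(1/jωC_HE + Z_IG*) then develops the electrode
EMI voltages

    V_S = I_GG*·Z_G + I_SG·Z_SG,   V_R = I_GG*·Z_G + I_RG·Z_RG

referenced to the recording-system IC ground. Two modeling choices here:

* The pipeline sets I_GG* = I_D_H (the low-Z_G approximation). A helper
  computes the actual ground-path share from path admittances so the quality
  of that approximation can be checked; it improves monotonically as Z_G
  shrinks.
* How the ground-node current divides between the signal-side and
  reference-side tissue branches is not observable and is not derivable
  without tissue geometry, so the split is an explicit input: fractions
  f_SG, f_RG of I_GG* with f_SG + f_RG ≤ 1. An optional helper derives
  fractions inversely proportional to |Z_SG|, |Z_RG|. Note that the
  admittance split makes f·Z equal on both branches and hence zeroes the
  differential pickup term by construction — that is exactly the staggered
  ideal the design guidelines aim for, which is why the default five-stage
  fixture uses fixed unequal fractions (0.25/0.20) instead.

Common/differential decomposition is CM = (V_S+V_R)/2, DM = V_S − V_R. The
differential interference at the amplifier keeps its two terms separate:
true DM pickup through the signal divider, and CM→DM conversion through the
divider imbalance; the imbalance bracket is the same expression in both the
common-mode analysis and the conversion term (the "Δ" of the conversion term
is read as the literal divider difference — the reading that makes the two
analyses mutually consistent; the residual divider-difference fraction is
reported so a manufacturing-mismatch reading can be computed from it too).

## Guideline checker

Distances are 3-D Euclidean between point sites; with multiple sites per
role the worst pair governs. "Ground at the midpoint" is evaluated per
signal–reference pair as the nearest ground site's distance from the pair
midpoint, allowed up to 10% of the pair span by default. All thresholds
(20 µm minimum spacing, 200 µm LFP bound, 10 kΩ ground bound, 5% attenuation
bound, matching tolerance) are configurable and echoed verbatim in the
report; the literature surveys a wide range of LFP spreads, so the 200 µm
upper bound is a default, not a law.

## Synthetic recordings

A recording is the exact sum of three components (kept separately as ground
truth, so composite − (spikes+LFP+line) is identically zero):

* **Spikes.** Biphasic difference-of-Gaussians template, 1.2 ms, normalized
  to unit peak-to-peak; Poisson times at 5 Hz with a 2 ms refractory gap;
  per-spike amplitudes drawn normally around each unit's mean. Defaults are
  two units at 947.55 µVpp (sd 62.94) and 312.32 µVpp (sd 49.68) — the
  amplitudes of the two units in the reference experiment.
* **LFP.** White Gaussian noise low-passed at 300 Hz (4th-order Butterworth,
  zero-phase) and scaled to a 100 µV rms default.
* **Line.** A 50 Hz sinusoid at the amplitude |V_CMI + V_DMI| the
  interference model produces for the stage's impedances.

Sampling default is 32 kS/s per channel (a 1.024 MSPS front end shared by 32
channels). Spectral estimation is Welch with a Hann window, 1 s segments,
50% overlap, one-sided density; these parameters ride along in `PSDResult`,
and the Parseval ratio (integrated density over signal power) is recorded as
a self-check. Spike peak-to-peak statistics are measured at ground-truth
times in a ±2 ms window, optionally after a 4th-order zero-phase high-pass
(300 Hz default in the stage experiment) — the standard spike-band treatment
that removes LFP and mains content; zero-phase filtering keeps the residual
50 Hz leakage at the sub-µV level even for a 100 mV line.

### Five-stage fixture and calibration

The packaged stage sequence uses the measured 1 kHz parallel impedances of
the reference experiment (reference bank 4.67e4 Ω at 4 electrodes →
2.17e4 Ω at 14; added cortical grounds 7.01e5, 8.73e5, 1.51e5 Ω), rescaled
capacitively to 50 Hz, over a 5 kΩ skull ground. The effective tissue
impedances Z_SG/Z_RG are nowhere published; the fixture uses tens of kΩ
shrinking with ground-electrode count (80/1 → 40/50 → 40/60 → 20/30 →
4/4.5 kΩ), nearly equal by stage 5 when the layout is staggered. The
absolute interference scale is anchored by one calibration scalar on V_IE
chosen so the stage-1 synthetic recording reproduces the measured stage-1
line density (4.43e-3 V²/Hz, via the Hann peak-density relation
A = √(2·1.5·df·PSD)); every later stage then follows from the circuit model
alone. The model reproduces the *monotone decrease* of the line across
stages; the published absolute densities for stages 2–5 are not reproduced
(and are not claimed — the in vivo spectral parameters and durations behind
them are unknown), so they serve only as the ratio anchors reported by the
acceptance script.

Default problem sizes (8 s stage recordings, 20–60 s for amplitude/statistic
recovery, one channel) were chosen so that every statistic they feed is
estimated well inside its stated tolerance: a 60 s recording recovers an
injected line amplitude to ~0.01%, and ~100 spikes put the peak-to-peak mean
within a couple of percent of its ground truth.

### What the generator does and does not emulate

It emulates the *measurement situation*: spike trains of fixed template shape
with amplitude jitter, a band-limited LFP floor, a deterministic mains line,
exact component bookkeeping, and bit-reproducibility from a seed. It does not
emulate electrode noise spectra, spike waveform diversity or bursting,
non-stationary interference (harmonics, ESD transients), electrode drift, or
ADC quantization. Passing tests therefore demonstrate the internal
consistency of the circuit model and the analysis chain, not fidelity to any
particular animal preparation.

## Numerical choices

* Dipole-field evaluation within 0.1 µm of a pole raises an error rather
  than clamping — silent clamping would hide configuration bugs.
* Impedance frequency equality is checked to 1e-9 relative; a zero impedance
  in a parallel bank short-circuits the bank (exact limit).
* The DC limit (f = 0) is permitted for impedances so the Randles cell's
  R_s + R_ct limit is expressible; capacitive elements still require f > 0.
* The electrode interface model is the textbook Randles cell
  R_s + (R_ct ∥ C_dl), without a Warburg element or constant-phase elements;
  fitting measured spectra is out of scope.
* The extreme-matching predicate uses an inclusive ≤ comparison at the
  boundary, making the pass/fail outcome deterministic for constructed
  boundary cases.

## Known limitations

* The amplifier common-mode and differential-mode input impedances are
  independent user inputs; real front ends tie them together in
  topology-specific ways.
* Z_IG* and the coupling capacitances are lumped user parameters; estimating
  them from geometry (distributed-capacitance formulas, parallel-plate
  approximations) is deliberately out of scope because such estimates are
  rarely better than order-of-magnitude.
* The stage fixture's tissue impedances and current-split fractions are
  plausible choices, not measurements; conclusions that depend on their
  precise values (anything beyond the monotone trend) should be re-derived
  with site-specific estimates.
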