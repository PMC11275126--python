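"""Named constants and fixture tables used across the package.

Literature-cited magnitudes live here as data for scenario construction —
they are inputs, never model outputs.
"""

from __future__ import annotations

# --- electrode geometry rules (meters) --------------------------------------
MIN_INTER_ELECTRODE_DISTANCE_M = 20e-6   # maximum neuron size: closer sites share the cell
MAX_SIGNAL_REFERENCE_DISTANCE_M = 200e-6  # minimum local LFP spread
DEFAULT_MIDPOINT_TOLERANCE_FRACTION = 0.10

# --- impedance-plan rules ----------------------------------------------------
DEFAULT_GROUND_IMPEDANCE_BOUND_OHM = 10e3  # skull-ground "kiloohm range"
DEFAULT_ATTENUATION_BOUND_PERCENT = 5.0
DEFAULT_EXTREME_MATCHING_FACTOR = 100.0

# --- typical common-mode interference magnitudes by ground placement (V) -----
CMI_GROUND_IN_CORTEX_V = 1e-3
CMI_GROUND_ON_HEAD_V = 10e-3
CMI_GROUND_ON_CHEST_V = 100e-3

# --- amplifier / signal scale references -------------------------------------
TYPICAL_CMRR_DB = 70.0
DETECTABLE_SIGNAL_RMS_V = 5e-6
OPA_INPUT_CAPACITANCE_F = 21e-12          # measured front-end input capacitance

# --- tissue -------------------------------------------------------------------
CORTICAL_RESISTIVITY_BAND_OHM_M = (1.65, 3.9)

# --- 32-channel reference experiment fixtures --------------------------------
SIGNAL_ELECTRODE_IMPEDANCE_1KHZ_OHM = 6.95e5  # mean magnitude, mostly capacitive
REFERENCE_CHANNEL_COUNT = 32

#: parallel reference/ground electrode impedances at 1 kHz per optimization
#: stage, and the measured 50 Hz line power densities (V²/Hz) they produced.
#: These are calibration fixtures for the synthetic re-enactment, not
#: predictions of the circuit model.
STAGE_FIXTURE_1KHZ = {
    1: {"n_reference": 0, "n_ground": 0, "Z_ref_parallel": None, "Z_gnd_added": None},
    2: {"n_reference": 4, "n_ground": 8, "Z_ref_parallel": 4.67e4, "Z_gnd_added": 7.01e5},
    3: {"n_reference": 14, "n_ground": 8, "Z_ref_parallel": 2.17e4, "Z_gnd_added": 7.01e5},
    4: {"n_reference": 14, "n_ground": 16, "Z_ref_parallel": 2.17e4, "Z_gnd_added": 8.73e5},
    5: {"n_reference": 14, "n_ground": 22, "Z_ref_parallel": 2.17e4, "Z_gnd_added": 1.51e5},
}

STAGE_LINE_PSD_V2_PER_HZ = {
    1: 4.43e-3,
    2: 1.56e-3,
    3: 4.30e-4,
    4: 1.15e-4,
    5: 4.04e-6,
}

#: measured spike statistics per stage: (neuron, stage) -> (mean pp µV, sd µV)
STAGE_SPIKE_PP_UV = {
    ("neuron1", 1): (947.55, 62.94),
    ("neuron2", 1): (312.32, 49.68),
    ("neuron1", 2): (950.05, 73.39),
    ("neuron2", 2): (343.30, 42.52),
    ("neuron1", 3): (955.83, 75.11),
    ("neuron2", 3): (349.68, 45.44),
}
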