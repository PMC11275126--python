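"""Re-enacting the five-stage interference-rejection experiment in silico.

Each stage changes the electrode configuration (reference bank, cortical
ground count, staggering); the circuit model turns those impedances into a
50 Hz amplitude at the amplifier, and a synthetic recording (spikes + LFP +
that line) is analyzed exactly like the real data: Welch density at 50 Hz
and ground-truth-aligned spike peak-to-peak statistics.
"""

from neuroemi.simulate import (
    calibrate_source_to_line_psd,
    default_coupling_network,
    default_stage_fixture,
    run_stage_experiment,
)

stages = default_stage_fixture()
net = calibrate_source_to_line_psd(stages, default_coupling_network())
table = run_stage_experiment(stages, net, seed=1, duration_s=8.0)

cols = ["stage", "model_line_amplitude_v", "line_psd_v2_per_hz",
        "neuron1_pp_mean_uv", "neuron2_pp_mean_uv"]
print(table[cols].to_string(index=False, float_format=lambda v: f"{v:.4g}"))
print()
first, last = table["line_psd_v2_per_hz"].iloc[0], table["line_psd_v2_per_hz"].iloc[-1]
print(f"50 Hz line density falls {first/last:,.0f}× from stage 1 to stage 5,")
print("while the spike amplitudes barely move: the interference chain is")
print("suppressed without touching the neural signal path.")
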