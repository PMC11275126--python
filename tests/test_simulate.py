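import math

import numpy as np
import pandas as pd
import pytest

from neuroemi.constants import STAGE_LINE_PSD_V2_PER_HZ
from neuroemi.simulate import (
    SpikeUnit,
    StageConfig,
    amplitude_for_peak_density,
    biphasic_template,
    calibrate_source_to_line_psd,
    default_coupling_network,
    default_spike_units,
    default_stage_fixture,
    line_amplitude_from_psd,
    psd_at_line,
    run_stage_experiment,
    spike_pp_stats,
    stage_interference_amplitude,
    synthesize_recording,
    welch_psd,
)

FS = 32_000.0


def quiet_recording(seed=7, duration=4.0, amp=0.0, **kw):
    """Recording with direct interference control, no circuit model."""
    return synthesize_recording(
        None, None, duration, FS, seed, interference_amplitude_v=amp, **kw
    )


class TestSynthesis:
    def test_same_seed_gives_bit_identical_output(self):
        a = quiet_recording(seed=3, amp=1e-3)
        b = quiet_recording(seed=3, amp=1e-3)
        assert np.array_equal(a.samples, b.samples)
        assert not np.array_equal(a.samples, quiet_recording(seed=4, amp=1e-3).samples)

    def test_components_sum_to_composite_exactly(self):
        rec = quiet_recording(amp=5e-3)
        gt = rec.ground_truth
        assert np.array_equal(rec.samples, gt.spikes + gt.lfp + gt.interference)

    def test_no_interference_means_no_line_above_background(self):
        rec = quiet_recording(amp=0.0, duration=8.0)
        psd = welch_psd(rec)
        line = psd_at_line(psd, 50.0)
        neighbors = psd.density[(np.abs(psd.frequencies - 50.0) > 2)
                                & (np.abs(psd.frequencies - 50.0) < 10)]
        assert line < 10 * neighbors.mean()

    def test_injected_amplitude_recovered_from_ground_truth_exactly(self):
        rec = quiet_recording(amp=2.5e-3, duration=2.0)
        x = rec.ground_truth.interference[0]
        # amplitude of a pure sinusoid over an integer number of periods
        assert math.sqrt(2.0) * np.sqrt(np.mean(x**2)) == pytest.approx(2.5e-3, rel=1e-6)

    def test_injected_amplitude_recovered_from_composite_psd(self):
        rec = quiet_recording(amp=2.5e-3, duration=10.0)
        a = line_amplitude_from_psd(welch_psd(rec), 50.0)
        assert a == pytest.approx(2.5e-3, rel=0.05)

    def test_validation_errors(self):
        with pytest.raises(ValueError, match="duration"):
            quiet_recording(duration=0.0)
        with pytest.raises(ValueError, match="2 kHz"):
            synthesize_recording(None, None, 1.0, 1000.0, 0)
        with pytest.raises(ValueError, match="spike-band"):
            synthesize_recording(None, None, 1.0, 8000.0, 0)

    def test_template_is_biphasic_unit_peak_to_peak(self):
        w = biphasic_template(FS)
        assert w.max() - w.min() == pytest.approx(1.0)
        assert w.min() < 0 < w.max()


class TestWelch:
    def test_sinusoid_power_integrates_to_half_amplitude_squared(self):
        t = np.arange(int(20 * FS)) / FS
        a = 3e-3
        x = a * np.sin(2 * np.pi * 50.0 * t + 0.3)
        psd = welch_psd(x, fs=FS)
        mask = np.abs(psd.frequencies - 50.0) <= 2.0
        df = psd.frequencies[1] - psd.frequencies[0]
        assert psd.density[mask].sum() * df == pytest.approx(a**2 / 2, rel=0.02)
        assert psd.parseval_ratio == pytest.approx(1.0, abs=0.02)

    def test_white_noise_density_is_flat_and_integrates_to_variance(self):
        rng = np.random.default_rng(11)
        sigma = 2e-4
        x = rng.normal(0, sigma, int(30 * FS))
        psd = welch_psd(x, fs=FS)
        df = psd.frequencies[1] - psd.frequencies[0]
        assert psd.density.sum() * df == pytest.approx(sigma**2, rel=0.05)
        lo = psd.density[(psd.frequencies > 100) & (psd.frequencies < 4000)].mean()
        hi = psd.density[(psd.frequencies > 8000) & (psd.frequencies < 15000)].mean()
        assert lo == pytest.approx(hi, rel=0.05)

    def test_zero_signal_gives_zero_density(self):
        psd = welch_psd(np.zeros(int(4 * FS)), fs=FS)
        assert np.all(psd.density == 0)

    def test_line_density_scales_with_amplitude_squared(self):
        d = []
        for a in (1e-3, 2e-3):
            rec = quiet_recording(amp=a, duration=8.0, lfp_rms_v=0.0)
            d.append(psd_at_line(welch_psd(rec), 50.0))
        assert d[1] / d[0] == pytest.approx(4.0, rel=0.01)

    def test_off_line_frequency_sees_background_only(self):
        rec = quiet_recording(amp=5e-3, duration=8.0)
        psd = welch_psd(rec)
        assert psd_at_line(psd, 50.0) > 1e3 * psd_at_line(psd, 137.0)

    def test_peak_density_inverts_amplitude_calibration(self):
        a = 2e-3
        rec = quiet_recording(amp=a, duration=8.0, lfp_rms_v=0.0)
        peak = psd_at_line(welch_psd(rec), 50.0)
        assert amplitude_for_peak_density(peak) == pytest.approx(a, rel=0.02)


class TestSpikeStats:
    def test_noiseless_train_recovers_amplitude_exactly(self):
        unit = SpikeUnit("u", pp_mean_v=500e-6, pp_sd_v=0.0, rate_hz=2.0)
        rec = quiet_recording(units=[unit], lfp_rms_v=0.0, duration=10.0)
        stats = spike_pp_stats(rec)
        row = stats.iloc[0]
        assert row["pp_mean_uv"] == pytest.approx(500.0, rel=1e-6)
        assert row["pp_sd_uv"] == pytest.approx(0.0, abs=1e-6)

    def test_amplitude_jitter_recovered(self):
        unit = SpikeUnit("u", pp_mean_v=500e-6, pp_sd_v=50e-6, rate_hz=20.0, refractory_s=5e-3)
        rec = quiet_recording(units=[unit], lfp_rms_v=0.0, duration=20.0, seed=5)
        stats = spike_pp_stats(rec)
        row = stats.iloc[0]
        assert row["n_spikes"] >= 200
        assert row["pp_sd_uv"] == pytest.approx(50.0, rel=0.20)

    def test_two_units_give_two_labeled_rows(self):
        rec = quiet_recording(duration=5.0)
        stats = spike_pp_stats(rec)
        assert list(stats["unit"]) == ["neuron1", "neuron2"]

    def test_highpass_removes_interference_bias(self):
        unit = SpikeUnit("u", pp_mean_v=500e-6, pp_sd_v=0.0, rate_hz=2.0)
        rec = quiet_recording(units=[unit], lfp_rms_v=0.0, duration=10.0, amp=50e-3)
        raw = spike_pp_stats(rec).iloc[0]["pp_mean_uv"]
        filt = spike_pp_stats(rec, highpass_hz=300.0).iloc[0]["pp_mean_uv"]
        assert abs(raw - 500.0) > 10 * abs(filt - 500.0)
        assert filt == pytest.approx(500.0, rel=0.05)


class TestStageExperiment:
    def test_modeled_amplitude_strictly_decreases_over_stages(self):
        stages = default_stage_fixture()
        net = default_coupling_network()
        amps = [stage_interference_amplitude(s, net) for s in stages]
        assert np.all(np.diff(amps) < 0)

    def test_calibration_hits_stage1_line_density(self):
        stages = default_stage_fixture()
        net = calibrate_source_to_line_psd(stages, default_coupling_network())
        rec = synthesize_recording(stages[0], net, 8.0, FS, 0, lfp_rms_v=0.0)
        peak = psd_at_line(welch_psd(rec), 50.0)
        assert peak == pytest.approx(STAGE_LINE_PSD_V2_PER_HZ[1], rel=0.05)

    def test_stage_table_decreases_and_keeps_spikes_stable(self):
        stages = default_stage_fixture()
        net = calibrate_source_to_line_psd(stages, default_coupling_network())
        table = run_stage_experiment(stages, net, seed=2, duration_s=4.0)
        psd_col = table["line_psd_v2_per_hz"].to_numpy()
        assert np.all(np.diff(psd_col) < 0)
        for unit in ("neuron1", "neuron2"):
            means = table[f"{unit}_pp_mean_uv"].to_numpy()
            sd = table[f"{unit}_pp_sd_uv"].to_numpy().max()
            assert means.max() - means.min() < sd

    def test_identical_stage_configs_give_identical_rows(self):
        stages = default_stage_fixture()
        net = default_coupling_network()
        table = run_stage_experiment([stages[2], stages[2]], net, seed=1, duration_s=2.0)
        a, b = table.drop(columns=["stage", "description"]).iloc[0], \
            table.drop(columns=["stage", "description"]).iloc[1]
        assert (a == b).all()

    def test_stage_order_permutes_rows(self):
        stages = default_stage_fixture()
        net = default_coupling_network()
        fwd = run_stage_experiment(stages[:3], net, seed=1, duration_s=2.0)
        rev = run_stage_experiment(stages[:3][::-1], net, seed=1, duration_s=2.0)
        assert list(rev["stage"]) == list(fwd["stage"])[::-1]
        assert rev["line_psd_v2_per_hz"].iloc[2] == fwd["line_psd_v2_per_hz"].iloc[0]

    def test_stage_config_requires_both_characterization_frequencies(self):
        good = default_stage_fixture()[1]
        with pytest.raises(ValueError, match="1000"):
            StageConfig(
                stage=2, description="", n_reference=4, n_ground=8,
                Z_ref_parallel={50.0: good.Z_ref_parallel[50.0]},
                Z_gnd_parallel=good.Z_gnd_parallel,
                Z_SG_eff=good.Z_SG_eff, Z_RG_eff=good.Z_RG_eff,
            )
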