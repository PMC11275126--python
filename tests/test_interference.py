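import numpy as np
import pytest

from conftest import make_setup, random_rc_impedance
from neuroemi.coupling import ElectrodeEMIEnvironment
from neuroemi.impedance import ComplexImpedance, resistor_impedance
from neuroemi.interference import (
    MatchingScheme,
    check_extreme_matching,
    cmi_at_inputs,
    cmi_differential,
    dmi_differential,
    interference_pipeline,
    rigorous_match_reference,
    shared_cm_impedance,
)
from neuroemi.simulate import default_coupling_network


def rigorous_setup(rng, n, f=50.0):
    """Random RC setup obeying exact rigorous matching: Z_R=Z_S/N, Z_N_CM=Z_P_CM/N."""
    zs = random_rc_impedance(rng, f)
    zp_cm = random_rc_impedance(rng, f)
    return make_setup(
        zs, ComplexImpedance(zs.value / n, f), random_rc_impedance(rng, f),
        random_rc_impedance(rng, f), random_rc_impedance(rng, f),
        z_p_cm=zp_cm, n=n,
    )


class TestCMIDividers:
    def test_zero_electrode_impedance_passes_common_mode_unattenuated(self):
        f = 50.0
        zero = ComplexImpedance(0j, f)
        setup = make_setup(zero, zero, resistor_impedance(1e3, f),
                           resistor_impedance(1e7, f), resistor_impedance(1e7, f))
        v_p, v_n = cmi_at_inputs(0.01, setup)
        assert v_p == pytest.approx(0.01) and v_n == pytest.approx(0.01)

    def test_zero_common_mode_gives_zero(self, simple_setup):
        assert cmi_at_inputs(0.0, simple_setup) == (0, 0)

    def test_dividers_match_direct_arithmetic(self, rng):
        setup = rigorous_setup(rng, 4)
        v_cm = 0.005 * np.exp(1j * 0.2)
        v_p, v_n = cmi_at_inputs(v_cm, setup)
        zp, zn = setup.Z_OP_P_CM.value, setup.Z_OP_N_CM.value
        assert v_p == pytest.approx(v_cm * zp / (zp + setup.Z_S.value), rel=1e-12)
        assert v_n == pytest.approx(v_cm * zn / (zn + setup.Z_R.value), rel=1e-12)


class TestMatchingIdentities:
    @pytest.mark.parametrize("n", [1, 4, 16, 32])
    def test_rigorous_matching_cancels_cmi_exactly(self, rng, n):
        for _ in range(250):
            setup = rigorous_setup(rng, n)
            v_cm = 0.01 * np.exp(1j * rng.uniform(0, 2 * np.pi))
            assert abs(cmi_differential(v_cm, setup)) <= 1e-12 * abs(v_cm)

    def test_extreme_matching_bounds_cmi(self, rng):
        f = 50.0
        for _ in range(200):
            zp_cm = random_rc_impedance(rng, f)
            zn_cm = shared_cm_impedance(zp_cm, 32)
            small = 1e-6 * abs(zn_cm.value)
            zs = ComplexImpedance(small * np.exp(-0.4j), f)
            zr = ComplexImpedance(small * np.exp(-0.9j), f)
            setup = make_setup(zs, zr, resistor_impedance(1e3, f),
                               zp_cm, zp_cm, z_p_cm=zp_cm, n=32)
            assert abs(cmi_differential(0.01, setup)) <= 1e-5 * 0.01

    def test_deliberate_mismatch_matches_divider_oracle(self, rng):
        setup = rigorous_setup(rng, 8)
        f = setup.frequency
        z_r_bad = ComplexImpedance(setup.Z_R.value * 1.10, f)
        bad = make_setup(setup.Z_S, z_r_bad, setup.Z_G, setup.Z_OP_P_DM,
                         setup.Z_OP_N_DM, z_p_cm=setup.Z_OP_P_CM, n=8)
        v_cm = 0.002
        zp, zn = bad.Z_OP_P_CM.value, bad.Z_OP_N_CM.value
        expected = v_cm * (zp / (zp + bad.Z_S.value) - zn / (zn + z_r_bad.value))
        out = cmi_differential(v_cm, bad)
        assert out == pytest.approx(expected, rel=1e-12)
        assert abs(out) > 0

    def test_cmi_vanishes_continuously_as_mismatch_shrinks(self, rng):
        setup = rigorous_setup(rng, 4)
        f = setup.frequency
        mags = []
        for eps in [0.2, 0.1, 0.05, 0.01, 0.001]:
            z_r = ComplexImpedance(setup.Z_R.value * (1 + eps), f)
            s = make_setup(setup.Z_S, z_r, setup.Z_G, setup.Z_OP_P_DM,
                           setup.Z_OP_N_DM, z_p_cm=setup.Z_OP_P_CM, n=4)
            mags.append(abs(cmi_differential(1.0, s)))
        assert np.all(np.diff(mags) < 0)
        assert mags[-1] < 1e-2 * mags[0]


class TestMatchingHelpers:
    def test_shared_cm_impedance_identity_at_one_channel(self):
        z = ComplexImpedance(7.6e6 * np.exp(-1.5j), 1000.0)
        assert shared_cm_impedance(z, 1).value == z.value

    def test_shared_cm_impedance_divides_by_channel_count(self):
        z = ComplexImpedance(-7.6e6j, 1000.0)
        out = shared_cm_impedance(z, 32)
        assert abs(out.value) == pytest.approx(237_500.0, rel=1e-12)
        assert out.frequency == 1000.0

    def test_rigorous_reference_matches_published_32_channel_value(self):
        """6.95×10⁵ Ω signal electrode, N=32 → 2.17×10⁴ Ω reference bank (3 s.f.)."""
        z_s = ComplexImpedance(-6.95e5j, 1000.0)
        z_r = rigorous_match_reference(z_s, 32)
        assert float(f"{abs(z_r.value):.3g}") == 2.17e4

    def test_rigorous_reference_preserves_phase(self):
        z_s = ComplexImpedance(6.95e5 * np.exp(-1.2j), 1000.0)
        z_r = rigorous_match_reference(z_s, 32)
        assert np.angle(z_r.value) == pytest.approx(-1.2, rel=1e-12)
        assert rigorous_match_reference(z_s, 1).value == z_s.value


class TestExtremeMatchingPredicate:
    def _setup(self, zs_mag, zn_cm_mag=1e8, f=50.0):
        zs = ComplexImpedance(-1j * zs_mag, f) if zs_mag else ComplexImpedance(0j, f)
        zp_cm = ComplexImpedance(-1j * zn_cm_mag, f)
        return make_setup(zs, zs, resistor_impedance(1e3, f),
                          zp_cm, zp_cm, z_p_cm=zp_cm, n=1)

    def test_zero_electrode_impedance_passes_with_infinite_margin(self):
        res = check_extreme_matching(self._setup(0.0))
        assert res.passed and res.margin == float("inf")

    def test_comparable_impedances_fail(self):
        assert not check_extreme_matching(self._setup(1e8)).passed

    def test_boundary_is_inclusive(self):
        res = check_extreme_matching(self._setup(1e6), factor=100.0)
        assert res.passed and res.margin == pytest.approx(1.0)

    def test_saturation_warning_when_common_mode_exceeds_range(self):
        res = check_extreme_matching(
            self._setup(1e3), v_cm_probe=0.1, input_range_bound=0.05
        )
        assert res.saturation_warning


class TestDMI:
    def test_balanced_dividers_leave_only_true_dm_pickup(self, rng):
        setup = rigorous_setup(rng, 16)
        rep = dmi_differential(0.01, 1e-4, setup)
        assert abs(rep.dmi_cm_conversion) <= 1e-14 * 0.01
        assert rep.V_DMI_OP_DIFF == pytest.approx(rep.dmi_true_dm)

    def test_pure_common_mode_reduces_to_cmi_conversion(self, rng):
        setup = rigorous_setup(rng, 4)
        bad = make_setup(setup.Z_S, ComplexImpedance(setup.Z_R.value * 1.2, 50.0),
                         setup.Z_G, setup.Z_OP_P_DM, setup.Z_OP_N_DM,
                         z_p_cm=setup.Z_OP_P_CM, n=4)
        rep = dmi_differential(0.01, 0.0, bad)
        assert rep.dmi_true_dm == 0
        assert rep.V_DMI_OP_DIFF == pytest.approx(cmi_differential(0.01, bad), rel=1e-12)

    def test_mixed_case_matches_term_oracle_and_sums_exactly(self, rng):
        from neuroemi.signal_path import transfer_factor

        setup = rigorous_setup(rng, 2)
        bad = make_setup(setup.Z_S, ComplexImpedance(setup.Z_R.value * 0.93, 50.0),
                         setup.Z_G, setup.Z_OP_P_DM, setup.Z_OP_N_DM,
                         z_p_cm=setup.Z_OP_P_CM, n=2)
        v_cm, v_dm = 0.02 * np.exp(0.4j), 3e-4 * np.exp(-0.8j)
        rep = dmi_differential(v_cm, v_dm, bad)
        assert rep.dmi_true_dm == pytest.approx(v_dm * transfer_factor(bad), rel=1e-12)
        assert rep.dmi_cm_conversion == pytest.approx(cmi_differential(v_cm, bad), rel=1e-12)
        assert rep.dmi_true_dm + rep.dmi_cm_conversion == rep.V_DMI_OP_DIFF


class TestPipeline:
    def env(self, zg=5e3, f=50.0):
        return ElectrodeEMIEnvironment(
            Z_G=resistor_impedance(zg, f),
            Z_SG=resistor_impedance(40e3, f),
            Z_RG=resistor_impedance(60e3, f),
            f_SG=0.25, f_RG=0.20,
        )

    def setup_50hz(self, rng):
        return rigorous_setup(rng, 32, f=50.0)

    def test_zero_source_gives_all_zero_report(self, rng):
        net = default_coupling_network().scaled_source(0.0)
        rep = interference_pipeline(net, self.env(), self.setup_50hz(rng))
        assert rep.V_EMI_ME_CM == 0 and rep.V_EMI_ME_DM == 0
        assert rep.V_CMI_OP_DIFF == 0 and rep.V_DMI_OP_DIFF == 0

    def test_linear_in_source_voltage(self, rng):
        net = default_coupling_network()
        setup = self.setup_50hz(rng)
        r1 = interference_pipeline(net, self.env(), setup)
        r2 = interference_pipeline(net.scaled_source(3.0), self.env(), setup)
        assert r2.total_at_amplifier == pytest.approx(3 * r1.total_at_amplifier, rel=1e-12)

    def test_lower_ground_impedance_reduces_common_mode_interference(self, rng):
        net = default_coupling_network()
        zs = ComplexImpedance(-1.39e7j, 50.0)
        zp_cm = ComplexImpedance(-1.516e8j, 50.0)
        # slight mismatch so the CMI residue is nonzero
        setup = make_setup(zs, ComplexImpedance(zs.value / 32 * 1.1, 50.0),
                           resistor_impedance(5e3, 50.0), zp_cm, zp_cm,
                           z_p_cm=zp_cm, n=32)
        r_hi = interference_pipeline(net, self.env(zg=5e3), setup)
        r_lo = interference_pipeline(net, self.env(zg=2.5e3), setup)
        assert abs(r_lo.V_CMI_OP_DIFF) < abs(r_hi.V_CMI_OP_DIFF)

    def test_end_to_end_matches_hand_chained_oracle(self, rng):
        from neuroemi.coupling import (
            body_emi_unshielded,
            cm_dm_decompose,
            electrode_emi_voltages,
            hardware_displacement_current,
        )

        net = default_coupling_network()
        env = self.env()
        setup = self.setup_50hz(rng)
        rep = interference_pipeline(net, env, setup)
        v_body = body_emi_unshielded(net)
        i = hardware_displacement_current(v_body, net)
        v_s, v_r = electrode_emi_voltages(i, env)
        v_cm, v_dm = cm_dm_decompose(v_s, v_r)
        expected = dmi_differential(v_cm, v_dm, setup)
        assert rep.total_at_amplifier == pytest.approx(expected.total_at_amplifier, rel=1e-12)

    def test_frequency_mismatch_rejected(self, rng):
        net = default_coupling_network(frequency=60.0)
        with pytest.raises(ValueError, match="Hz"):
            interference_pipeline(net, self.env(f=50.0), rigorous_setup(rng, 4, f=50.0))
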