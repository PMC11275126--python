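"""From a 230 V mains line to microvolts of interference at the amplifier.

The chain: capacitive coupling puts volts of common-mode swing on the body;
a nanoamp-scale displacement current takes the recording-hardware branch to
ground; that current develops voltages across the ground path and the
inter-electrode tissue, part common-mode, part differential; electrode/input
impedance dividers decide what the amplifier finally sees.
"""

from neuroemi import ElectrodeEMIEnvironment, ShieldCoupling, interference_pipeline
from neuroemi.coupling import body_emi_shielded, body_emi_unshielded, hardware_displacement_current
from neuroemi.impedance import resistor_impedance
from neuroemi.simulate import default_coupling_network, default_stage_fixture, stage_recording_setup

net = default_coupling_network()
v_body = body_emi_unshielded(net)
i_dh = hardware_displacement_current(v_body, net)
print(f"body common-mode voltage (unshielded): {abs(v_body):.3f} V")
print(f"hardware-branch displacement current:  {abs(i_dh)*1e9:.2f} nA")

shielded = net.__class__(**{**net.__dict__, "shield": ShieldCoupling(1e-12, 50e-12, 1.0)})
print(f"body voltage behind a grounded shield: {abs(body_emi_shielded(shielded))*1e9:.2f} nV")

env = ElectrodeEMIEnvironment(
    Z_G=resistor_impedance(5e3, 50.0),
    Z_SG=resistor_impedance(40e3, 50.0),
    Z_RG=resistor_impedance(60e3, 50.0),
    f_SG=0.25, f_RG=0.20,
)
setup = stage_recording_setup(default_stage_fixture()[1], 50.0)
rep = interference_pipeline(net, env, setup)
print()
print(f"electrode common-mode EMI:        {abs(rep.V_EMI_ME_CM)*1e6:8.2f} µV")
print(f"electrode differential-mode EMI:  {abs(rep.V_EMI_ME_DM)*1e6:8.2f} µV")
print(f"CMI residue at amplifier (DM):    {abs(rep.V_CMI_OP_DIFF)*1e6:8.2f} µV")
print(f"DMI at amplifier:                 {abs(rep.V_DMI_OP_DIFF)*1e6:8.2f} µV")
print(f"  of which true DM pickup:        {abs(rep.dmi_true_dm)*1e6:8.2f} µV")
print(f"  of which CM→DM conversion:      {abs(rep.dmi_cm_conversion)*1e6:8.2f} µV")
print()
print("Unequal tissue paths (40 vs 60 kΩ) make part of the common mode appear")
print("differentially — interference no amplifier CMRR can reject afterwards.")
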