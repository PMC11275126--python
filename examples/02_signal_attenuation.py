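"""How much neural signal survives the electrode → amplifier divider.

The electrode path impedance and the amplifier's differential-mode input
impedance form a voltage divider.  We sweep commercial-probe impedances
(5 kΩ – 2.5 MΩ at 1 kHz) against two published front-end input impedances.
"""

from neuroemi import ComplexImpedance, RecordingSetup, attenuation_ratio, shared_cm_impedance
from neuroemi.impedance import resistor_impedance


def setup(ze_ohm, zin_ohm, f=1000.0):
    ze, zin = ComplexImpedance(ze_ohm, f), ComplexImpedance(zin_ohm, f)
    return RecordingSetup(Z_S=ze, Z_R=ze, Z_G=resistor_impedance(1e3, f),
                          Z_OP_P_DM=zin, Z_OP_N_DM=zin, Z_OP_P_CM=zin,
                          Z_OP_N_CM=shared_cm_impedance(zin, 1), N=1)


print(f"{'electrode |Z|':>14} {'input |Z|':>12} {'attenuation':>12}")
for zin in (14.9e6, 6.6e6):
    for ze in (5e3, 100e3, 695e3, 2.5e6):
        att = attenuation_ratio(setup(ze, zin))
        print(f"{ze/1e3:11.0f} kΩ {zin/1e6:9.1f} MΩ {att:11.2f}%")

print()
print("A low-impedance electrode into a high-impedance input loses well under")
print("a percent of the signal; a 2.5 MΩ electrode into a 6.6 MΩ input loses")
print("about a quarter — the practical bounds of the published 0.03–27% range.")
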