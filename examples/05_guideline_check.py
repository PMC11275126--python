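"""Checking a probe layout and impedance plan against the six design rules.

A good layout (100 µm signal–reference span, ground at the midpoint, matched
impedances) passes everything; squeezing the electrodes to 10 µm or leaving
a megaohm ground path trips the relevant rules.
"""

from neuroemi import ComplexImpedance, ElectrodeSite, MatchingScheme, RecordingSetup, check_all, shared_cm_impedance
from neuroemi.impedance import resistor_impedance

UM, F, N = 1e-6, 1000.0, 32


def probe(span_um=100.0, gnd_um=None):
    gnd = span_um / 2 if gnd_um is None else gnd_um
    return [
        ElectrodeSite("sig", (0, 0, 0), "signal"),
        ElectrodeSite("ref", (span_um * UM, 0, 0), "reference"),
        ElectrodeSite("gnd", (gnd * UM, 0, 0), "ground"),
    ]


def plan(zg_ohm=5e3):
    z_s = ComplexImpedance(-6.95e5j, F)
    z_in = ComplexImpedance(-7.6e6j, F)
    return RecordingSetup(Z_S=z_s, Z_R=ComplexImpedance(z_s.value / N, F),
                          Z_G=resistor_impedance(zg_ohm, F),
                          Z_OP_P_DM=z_in, Z_OP_N_DM=z_in, Z_OP_P_CM=z_in,
                          Z_OP_N_CM=shared_cm_impedance(z_in, N), N=N)


scheme = MatchingScheme("rigorous", N=N)

for label, sites, setup in [
    ("well-designed probe", probe(), plan()),
    ("electrodes 10 µm apart", probe(span_um=10.0), plan()),
    ("1 MΩ ground path", probe(), plan(zg_ohm=1e6)),
]:
    rep = check_all(sites, setup, scheme)
    verdicts = " ".join(f"G{r.guideline}:{r.status}" for r in rep.results)
    print(f"{label:24} -> {verdicts}")

print()
print("G1/G2 police electrode spacing (neuron size vs LFP spread), G3 the")
print("ground midpoint, G4–G6 the ground, attenuation and matching budgets.")
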