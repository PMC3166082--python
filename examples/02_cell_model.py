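"""Simulate lysosomal ion trapping for three archetypal compounds.

Prints the steady-state lysosome/external concentration ratio (the CLys
descriptor divided by the external concentration) and the time to reach
95 % of steady state, compared against the standard 30-minute incubation.
"""

from fiasma import CellModelParams, SpeciationProfile, clys_descriptor, required_incubation

params = CellModelParams.default()  # external pH 7.4, lysosome pH 5.0, 10 uM outside

cases = {
    "weak base (pKa 9, logP 3)": (SpeciationProfile("monobase", pka_base1=9.0), 3.0),
    "very lipophilic base (pKa 9, logP 8)": (SpeciationProfile("monobase", pka_base1=9.0), 8.0),
    "bibase (pKa 10/9, logP 3)": (SpeciationProfile("bibase", pka_base1=10.0, pka_base2=9.0), 3.0),
    "acid (pKa 4, logP 2)": (SpeciationProfile("monoacid", pka_acid=4.0), 2.0),
}

for name, (profile, logp) in cases.items():
    clys = clys_descriptor(profile, params, logp)
    t95 = required_incubation(profile, params, logp, cap_min=1e5)
    slow = "slow accumulator (> 30 min)" if t95 > 30 else "fast (<= 30 min window)"
    print(f"{name}:")
    print(f"  CLys = {clys:9.1f} uM  (external 10 uM -> {clys / 10:7.1f}x enrichment)")
    print(f"  t95  = {t95:9.1f} min  -> {slow}")

print()
print("Weak bases are trapped in the acidic lysosome; acids are excluded.")
print("Very high lipophilicity or a second basic nitrogen slows accumulation,")
print("which is why such compounds need prolonged incubation in the assay.")
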