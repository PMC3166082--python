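"""Compute lysosomotropism descriptors for a handful of compounds.

Builds a tiny compound table in memory, derives the four model descriptors
and evaluates the Rule-of-Five. The printed matrix is what the classifier
consumes.
"""

from fiasma import CompoundRecord, CompoundTable, compute_descriptors, lipinski_violation

table = CompoundTable(
    [
        # a lipophilic weak base (classic cationic amphiphilic drug)
        CompoundRecord(id="base1", name="lipophilic monobase", mw=366.3, logp=5.45,
                       pka_base1=9.04, vsa_pol=45.0, hbd=1, hba=3),
        # a carboxylic acid: anionic at physiological pH, excluded from lysosomes
        CompoundRecord(id="acid1", name="aryl acid", mw=228.2, logp=2.1,
                       pka_acid=4.2, vsa_pol=60.0, hbd=1, hba=3),
        # no ionizable group in the relevant range
        CompoundRecord(id="neut1", name="neutral ether", mw=194.3, logp=3.3,
                       vsa_pol=12.0, hbd=0, hba=1),
    ]
)

matrix, flags = compute_descriptors(table)
print(matrix[["logp_logweight", "pka_sum_basic_mod", "pka_most_acidic", "si_vsa_pol"]].round(4))
print()
print("Imputation flags for acid1:",
      {k: v for k, v in flags.loc["acid1"].items() if v == "imputed"})
for rec in table:
    res = lipinski_violation(rec.mw, rec.logp, rec.hbd, rec.hba)
    print(f"{rec.id}: Rule-of-Five violations = {res.count} (violated: {res.violated})")
print()
print("Higher logp_logweight and pka_sum_basic_mod push a compound toward the")
print("functional-inhibitor class; a low most-acidic pKa (a real acid) pulls it out.")
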