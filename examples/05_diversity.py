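"""Relative structural diversity (div_rel) of compound sets.

Compares a close-analogue series against a set of unrelated scaffolds:
div_rel = clusters at 0.85 Tanimoto similarity / number of compounds.
"""

from rdkit import Chem

from fiasma import diversity_of

subs = ["F", "Cl", "Br", "I", "C", "CC", "OC", "O", "N", "C(C)C", "CCC", "CCO"]
analogues = {f"a{i}": Chem.MolFromSmiles(f"CCN(CC)CCOc1ccc({s})cc1") for i, s in enumerate(subs)}
scaffolds = [
    "c1ccncc1", "C1CCNCC1", "CC(=O)Oc1ccccc1C(=O)O", "CN1CCN(CC1)c1ccccc1",
    "OC(=O)CCCCCCC", "c1ccc2ccccc2c1", "C1CCC2(CC1)OCCO2", "CC(C)Cc1ccc(C)cc1",
    "NC(=O)c1cnccc1", "OCC1OC(O)C(O)C(O)C1O", "CSc1nnc(C)s1", "ClC(Cl)c1ccccc1",
]
mixed = {f"s{i}": Chem.MolFromSmiles(s) for i, s in enumerate(scaffolds)}

for name, mols in (("12 close analogues of one amine", analogues),
                   ("12 unrelated scaffolds", mixed)):
    dr, solution = diversity_of(mols)
    print(f"{name}: {solution.n_clusters} clusters at 0.85 similarity "
          f"-> div_rel = {dr:.3f}")
print()
print("div_rel near 1 means nearly every compound is its own structural class;")
print("a low value means the set is dominated by one scaffold family.")
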