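"""Empirical flammability of the 17 phthalate plasticizers.

For each molecule the char residue CR = 1200 * sum(CFT) / M is computed from
its molar mass (the phthalate moiety contributes CFT = 2), and the limited
oxygen index follows as LOI = 17.5 + 0.4 * CR.  Higher LOI means a larger
oxygen fraction is needed to sustain burning, i.e. better flame retardancy;
heavier esters dilute the char-forming core and burn more readily.
"""

import ecoqsar as eq

table1 = eq.load_fixture("table1")
print(f"{'molecule':8s} {'M (g/mol)':>10s} {'CR':>8s} {'LOI (%)':>8s}")
for _, row in table1.iterrows():
    mol = eq.parse_structure(row["smiles"], row["id"])
    result = eq.loi_from_molecule(mol)
    print(f"{row['id']:8s} {eq.molar_mass(mol):10.2f} {result.CR:8.3f} "
          f"{result.LOI_rounded:8.2f}")
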