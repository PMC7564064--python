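"""Derivative design and the eco-friendliness screening funnel.

Substituents are attached at the two terminal side-chain sites of DMP and
DAP, and candidates are screened on the reference effect table: every
survivor must improve all four effects, gain more than 5% LOI, and stay
non-bioaccumulative (logBCF < 3.30).  Joining the eco-friendliness table
adds the semi-volatility band on logKOA and the stability rule (Freq > 0),
which trims one more candidate.
"""

import warnings

import ecoqsar as eq
from ecoqsar.design import SubstitutionPlan, enumerate_derivatives, screen
from ecoqsar.fixtures import group_fragments, load_sites

sites = load_sites()["DAP"]
plan = SubstitutionPlan("DAP", sites["smiles"], sites["sites"],
                        group_fragments(), mode="single")
derivs = enumerate_derivatives(plan)
print(f"enumerated {len(derivs)} single-substitution DAP derivatives, e.g.:",
      ", ".join(r.id for r in derivs[:4]))

table7 = eq.load_fixture("table7")
records = table7[table7["parent"].notna()]
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    screened = screen(records)
survivors = screened[screened["passes"]]
print(f"\nscreening funnel: {len(records)} candidates -> {len(survivors)} pass")
print("\n".join("  " + s for s in survivors["id"]))

eco = eq.load_fixture("table8").set_index("id")[["logKOA", "freq"]]
joined = records.set_index("id").join(eco, how="inner").reset_index()
final = screen(joined)
print(f"\nwith logKOA band [6.5, 10] and Freq > 0: "
      f"{len(joined)} -> {int(final['passes'].sum())} eco-friendly flame retardants")
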