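"""Comprehensive evaluation of the 17 plasticizers by the ideal-point method.

LOI (flammability, larger better), raw fish LC50 (biotoxicity, larger =
less toxic) and logBCF (bio-enrichment, smaller better) are min-max
normalized and each molecule scored by its weighted euclidean distance from
the all-ideal point, with weights 40/30/30.  Smaller Z = closer to the
ideal plasticizer; the ranking identifies which PAEs are least problematic
across all three effects at once.
"""

import ecoqsar as eq

table1 = eq.load_fixture("table1").set_index("id")
result = eq.score_table(table1)
ranked = eq.rank_by_score(result)

print("rank  molecule    Z")
for rank, (mol, z) in enumerate(ranked.items(), 1):
    print(f"{rank:4d}  {mol:10s} {z:.3f}")
print("\nbest:", ranked.index[0], "- worst:", ranked.index[-1])
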