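# Modification sites on the two parent plasticizers.
#
# Site labels 1 and 2 name the terminal side-chain carbons of each parent
# (the H-bearing carbons at the end of each ester side chain).  Atom indices
# refer to the heavy-atom order of the SMILES given here, which is the
# deterministic order produced by parse_structure.  Edit this file to move
# the substitution sites.
DMP:
  smiles: COC(=O)c1ccccc1C(=O)OC
  sites:
    1: 0    # methyl carbon of the first ester
    2: 13   # methyl carbon of the second ester
DAP:
  smiles: C=CCOC(=O)c1ccccc1C(=O)OCC=C
  sites:
    1: 0    # terminal vinyl carbon of the first allyl chain
    2: 17   # terminal vinyl carbon of the second allyl chain
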