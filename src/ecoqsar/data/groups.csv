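group,volume,fragment_smiles
H,1.0,[*][H]
CH3,15.0,[*]C
CH=CH2,27.0,[*]C=C
CH2CH3,29.1,[*]CC
OCH3,31.0,[*]OC
SH,33.1,[*]S
CH2CH2CH3,43.1,[*]CCC
NO2,46.0,[*][N+](=O)[O-]
CH2NO2,60.0,[*]C[N+](=O)[O-]
CH2C6H5,91.1,[*]Cc1ccccc1
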