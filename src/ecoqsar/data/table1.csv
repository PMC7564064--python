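id,name,smiles,split,LOI,LC50,logBCF,logHL,logKOA,Z
DMP,dimethyl phthalate,COC(=O)c1ccccc1C(=O)OC,train,22.44,40.822,0.723,3.617,6.694,0.371
DIPrP,diisopropyl phthalate,CC(C)OC(=O)c1ccccc1C(=O)OC(C)C,train,21.34,4.568,1.534,3.179,7.376,0.599
DEP,diethyl phthalate,CCOC(=O)c1ccccc1C(=O)OCC,test,21.82,12.471,1.264,3.156,7.505,0.526
DBP,di-n-butyl phthalate,CCCCOC(=O)c1ccccc1C(=O)OCCCC,train,20.95,1.113,2.636,2.734,8.631,0.712
DIPP,di-isopentyl phthalate,CC(C)CCOC(=O)c1ccccc1C(=O)OCCC(C)C,test,20.63,0.398,3.260,2.904,9.504,0.794
BBP,benzyl butyl phthalate,CCCCOC(=O)c1ccccc1C(=O)OCc1ccccc1,train,20.57,0.911,2.788,2.915,9.018,0.760
DIBP,diisobutyl phthalate,CC(C)COC(=O)c1ccccc1C(=O)OCC(C)C,train,20.95,1.356,2.379,3.182,8.412,0.692
DNOP,di-n-octyl phthalate,CCCCCCCCOC(=O)c1ccccc1C(=O)OCCCCCCCC,test,19.96,0.008,2.988,2.655,12.079,0.845
DUP,diundecyl phthalate,CCCCCCCCCCCOC(=O)c1ccccc1C(=O)OCCCCCCCCCCC,train,19.52,0.000183,1.330,1.398,14.068,0.818
DIHP,di-isoheptyl phthalate,CC(C)CCCCOC(=O)c1ccccc1C(=O)OCCCCC(C)C,train,20.15,0.028,3.255,2.501,11.122,0.844
DTDP,ditridecyl phthalate,CCCCCCCCCCCCCOC(=O)c1ccccc1C(=O)OCCCCCCCCCCCCC,test,19.31,0.0000146,0.964,0.924,15.535,0.841
DHP,di-n-hexyl phthalate,CCCCCCOC(=O)c1ccccc1C(=O)OCCCCCC,train,20.37,0.095,2.793,1.639,9.799,0.784
DPP,di-n-pentyl phthalate,CCCCCOC(=O)c1ccccc1C(=O)OCCCCC,train,20.63,0.327,2.001,3.063,9.674,0.703
DAP,diallyl phthalate,C=CCOC(=O)c1ccccc1C(=O)OCC=C,train,21.40,5.323,1.798,3.895,8.032,0.605
DIHxP,di-iso-hexyl phthalate,CC(C)CCCOC(=O)c1ccccc1C(=O)OCCCC(C)C,train,20.37,0.116,3.908,2.623,10.239,0.880
DPrP,di-n-propyl phthalate,CCCOC(=O)c1ccccc1C(=O)OCCC,train,21.34,3.749,1.825,3.362,8.053,0.617
DMEP,dimethoxyethyl phthalate,COCCOC(=O)c1ccccc1C(=O)OCCOC,train,20.90,124.130,0.402,9.544,9.766,0.311
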