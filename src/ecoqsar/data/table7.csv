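id,parent,Z,Z_decrease_pct,LOI,LOI_increase_pct,logLC50,logLC50_increase_pct,logBCF,logBCF_decrease_pct
DMP,,0.371,,22.44,,1.61,,0.723,
DMP-1-CH2NO2,DMP,0.085,77.09,23.39,4.23,1.76,9.50,0.161,77.73
DMP-1-NO2,DMP,0.234,36.93,22.92,2.13,1.98,22.67,0.372,48.55
DMP-1-CH3-2-CH2NO2,DMP,0.145,60.92,23.12,3.03,2.29,42.48,0.353,51.18
DMP-1-CH3-2-NO2,DMP,0.292,21.29,22.66,0.98,2.17,34.97,0.556,23.10
DAP,,0.605,,21.40,,0.73,,1.798,
DAP-1-CH2NO2,DAP,0.325,46.28,22.23,3.86,2.28,212.47,1.007,43.99
DAP-1-SH,DAP,0.519,14.21,21.82,1.94,1.13,54.52,1.360,24.36
DAP-2-CH2NO2,DAP,0.279,53.88,22.52,5.24,2.27,210.41,0.162,90.99
DAP-2-NO2,DAP,0.293,51.57,22.36,4.50,1.94,165.89,0.183,89.82
DAP-2-SH,DAP,0.557,7.93,21.64,1.13,0.94,28.63,1.604,10.79
DAP-1-NO2-2-CH2C6H5,DAP,0.301,50.25,22.65,5.83,1.66,127.81,1.182,34.26
DAP-1-NO2-2-CH2CH3,DAP,0.365,39.67,22.57,5.49,1.88,157.95,1.482,17.58
DAP-1-NO2-2-CH2NO2,DAP,0.164,72.89,23.18,8.30,2.55,249.45,1.324,26.36
DAP-1-NO2-2-CH3,DAP,0.471,22.15,21.65,1.15,0.92,26.30,0.830,53.84
DAP-1-NO2-2-CH=CH2,DAP,0.447,26.12,22.18,3.63,2.03,177.81,0.696,61.29
DAP-1-NO2-2-NO2,DAP,-0.172,128.43,23.35,9.12,3.20,338.22,0.761,57.68
DAP-1-NO2-2-OCH3,DAP,0.340,43.80,22.54,5.32,1.83,150.96,1.401,22.08
DAP-1-NO2-2-SH,DAP,0.497,17.85,21.72,1.47,0.96,30.96,1.557,13.40
DAP-2-CH=CH2-1-CH2NO2,DAP,0.353,41.65,21.63,1.09,0.95,30.41,0.898,50.06
DAP-2-CH=CH2-1-CH3,DAP,0.529,12.56,21.56,0.74,0.90,23.70,1.366,24.03
DAP-2-CH=CH2-1-NO2,DAP,0.399,34.05,22.53,5.27,1.67,128.49,1.166,35.15
DAP-2-CH=CH2-1-OCH3,DAP,0.602,0.50,21.79,1.80,0.94,28.08,1.393,22.53
DAP-2-CH=CH2-1-SH,DAP,0.543,10.25,21.59,0.89,0.84,14.38,1.459,18.85
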