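group,comprehensive_effect_pct,group_properties_pct,flame_retardancy_pct,biotoxicity_pct,concentration_pct,weighted_comprehensive_effect_pct
CH3,29.23,655.85,1.48,31.86,38.04,21.56
CH2CH3,39.67,838.76,5.49,157.95,17.58,54.86
CH2C6H5,50.25,1566.12,5.83,127.81,34.26,50.95
NO2,45.42,941.61,4.43,134.29,40.26,54.14
CH2NO2,58.79,1170.32,4.29,125.79,56.72,56.47
SH,12.56,750.52,1.36,32.12,16.85,15.23
OCH3,22.15,738.53,3.56,89.52,22.31,34.97
CH=CH2,20.86,727.88,2.24,67.15,35.32,31.63
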