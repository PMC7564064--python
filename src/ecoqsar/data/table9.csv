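id,parent,site1_group,site2_group,logP,logP_increase_pct,coupling_value
DMP,,,,1.54,0.00,0.00
DAP,,,,3.06,0.00,0.00
DMP-1-CH2NO2,DMP,CH2NO2,,1.01,-34.42,1335.65
DMP-1-NO2,DMP,NO2,,0.56,-63.64,1001.93
DMP-1-CH3-2-CH2NO2,DMP,CH3,CH2NO2,1.30,-15.58,828.85
DMP-1-CH3-2-NO2,DMP,CH3,NO2,0.84,-45.45,655.14
DAP-1-CH2NO2,DAP,CH2NO2,,2.85,-6.86,1348.02
DAP-1-SH,DAP,SH,,2.55,-16.67,727.61
DAP-2-CH2NO2,DAP,,CH2NO2,3.04,-0.65,1350.81
DAP-2-NO2,DAP,,NO2,2.93,-4.25,1028.59
DAP-2-SH,DAP,,SH,3.09,0.98,735.53
DAP-1-NO2-2-CH2C6H5,DAP,NO2,CH2C6H5,4.37,42.81,1566.12
DAP-1-NO2-2-CH2CH3,DAP,NO2,CH2CH3,3.18,3.92,838.76
DAP-1-NO2-2-CH2NO2,DAP,NO2,CH2NO2,2.38,-22.22,1180.82
DAP-1-NO2-2-CH3,DAP,NO2,CH3,2.77,-9.48,671.29
DAP-1-NO2-2-CH=CH2,DAP,NO2,CH=CH2,2.91,-4.90,810.75
DAP-1-NO2-2-NO2,DAP,NO2,NO2,2.28,-25.49,1019.05
DAP-1-NO2-2-OCH3,DAP,NO2,OCH3,1.96,-35.95,842.61
DAP-1-NO2-2-SH,DAP,NO2,SH,2.43,-20.59,873.55
DAP-1-NO2-2-CH2CH2CH3,DAP,NO2,CH2CH2CH3,3.60,17.65,1005.22
DAP-2-CH=CH2-1-CH2NO2,DAP,CH2NO2,CH=CH2,3.37,10.13,977.80
DAP-2-CH=CH2-1-CH3,DAP,CH3,CH=CH2,3.75,22.55,468.12
DAP-2-CH=CH2-1-NO2,DAP,NO2,CH=CH2,2.91,-4.90,810.75
DAP-2-CH=CH2-1-OCH3,DAP,OCH3,CH=CH2,2.60,-15.03,634.45
DAP-2-CH=CH2-1-SH,DAP,SH,CH=CH2,3.07,0.33,665.39
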