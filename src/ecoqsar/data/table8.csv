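id,logHL,logHL_decrease_pct,logKOA,logKOA_increase_pct,freq,energy_gap,energy_gap_increase_pct
DAP,3.895,0.00,8.032,0.00,17.30,0.203,0.00
DAP-2-CH2NO2,3.875,0.51,6.282,-21.79,9.38,0.195,-3.89
DAP-1-NO2-2-CH2C6H5,3.643,6.47,6.902,-14.07,12.33,0.154,-23.84
DAP-1-NO2-2-CH2CH3,3.678,5.57,7.121,-11.34,12.94,0.156,-22.97
DAP-1-NO2-2-CH2NO2,3.624,6.96,6.936,-13.65,7.75,0.154,-23.91
DAP-1-NO2-2-NO2,3.620,7.06,7.087,-11.77,21.69,0.127,-37.42
DAP-1-NO2-2-OCH3,3.527,9.45,7.523,-6.34,11.70,0.175,-13.40
DAP-2-CH=CH2-1-NO2,3.434,11.84,7.748,-3.54,20.13,0.162,-20.26
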