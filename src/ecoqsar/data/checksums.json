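{
 "groups.csv": "5ed2a5c0ffea63144f75d9e66b0706b4e925eb7f31349ecce56826901d83353c",
 "table1.csv": "bff7d36af05f66c24d21e985b4cb6e21ddf416b92903f30632552d8f2b934baf",
 "table10.csv": "2c5cd7f14ad6b04f281a1f2047a5224127eb8490c9a2c84771b1ab989c9b2065",
 "table7.csv": "81a1fe43b1bc125fa8da42b8ca93fb0ddce3cd21dca88ba816f3d84b384852f0",
 "table8.csv": "c6b94bf965b2b69c1a8aef5e783e04397bd2c596932382cf2515efa75a13d6f4",
 "table9.csv": "ef08c19a24c26cb68e4b29b3864a0d9a3c77c8d3110668270e0009a2515bf355"
}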