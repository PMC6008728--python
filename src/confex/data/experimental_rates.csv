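temp_C,kex_s1,kex_sigma_s1,pE,pE_sigma
1.0,649,50,0.047,0.002
5.3,1099,57,0.047,0.002
10.4,2240,122,0.038,0.005
15.4,3871,79,0.035,0.002
20.4,6100,350,0.036,0.006
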