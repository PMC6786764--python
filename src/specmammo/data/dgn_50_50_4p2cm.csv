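# monoenergetic normalised glandular dose coefficients
# breast_thickness_cm: 4.2
# glandularity: 0.5
energy_keV,dgn_mgy_per_r
15,0.1
20,0.37
25,0.6
30,0.75
35,0.85
40,0.92
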