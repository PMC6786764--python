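# mass energy-absorption coefficient of dry air
energy_keV,muen_per_rho_cm2_g
15,1.334
20,0.5389
25,0.2703
30,0.1537
35,0.0995
40,0.0683
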