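# material: 50/50 glandular/adipose breast tissue
# density_g_cm3: 0.982
# two-term fit anchored to mu(25 keV)=0.466 /cm and mu(35 keV)=0.287 /cm
energy_keV,mu_per_cm
15,1.488240231
16,1.258724624
17,1.080065159
18,0.9389213238
19,0.8259410016
20,0.7344358515
21,0.6595365274
22,0.597640722
23,0.5460446184
24,0.5026919375
25,0.466
26,0.4347371992
27,0.4079354041
28,0.3848264765
29,0.3647956843
30,0.347347116
31,0.3320777265
32,0.3186576651
33,0.3068152258
34,0.2963252321
35,0.287
36,0.2786822526
37,0.2712395245
38,0.2645597124
39,0.2585475154
40,0.2531215686
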