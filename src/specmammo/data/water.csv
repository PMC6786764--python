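# material: liquid water
# density_g_cm3: 1.0
# two-term fit anchored to mu(25 keV)=0.5295 /cm and mu(35 keV)=0.3137 /cm
energy_keV,mu_per_cm
15,1.761899117
16,1.485198178
17,1.269808723
18,1.099647607
19,0.9634400456
20,0.8531226634
21,0.7628250425
22,0.6882042895
23,0.6260007187
24,0.5737353079
25,0.5295
26,0.4918099866
27,0.4594981017
28,0.4316382884
29,0.4074894339
30,0.386453674
31,0.3680451027
32,0.3518660566
33,0.3375889706
34,0.3249423748
35,0.3137
36,0.3036722353
37,0.294699382
38,0.2866462901
39,0.279398066
40,0.2728566173
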