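# material: calcium (elemental)
# density_g_cm3: 1.55
# two-term fit anchored to mu(25 keV)=10.650 /cm and mu(35 keV)=4.097 /cm
energy_keV,mu_per_cm
15,48.0731298
16,39.67080704
17,33.13027369
18,27.96314768
19,23.82705801
20,20.47715159
21,17.73516684
22,15.4692271
23,13.58034851
24,11.99325289
25,10.65
26,9.505502048
27,8.524316778
28,7.678323466
29,6.945017427
30,6.306243863
31,5.74724772
32,5.255953518
33,4.822414385
34,4.438386848
35,4.097
36,3.792496098
37,3.52002572
38,3.275484889
39,3.055384739
40,2.856746587
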