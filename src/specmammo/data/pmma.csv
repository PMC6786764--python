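# material: polymethyl methacrylate
# density_g_cm3: 1.19
# two-term fit anchored to mu(25 keV)=0.4799 /cm and mu(35 keV)=0.3139 /cm
energy_keV,mu_per_cm
15,1.42789932
16,1.215052445
17,1.049368248
18,0.9184750824
19,0.813700035
20,0.7288405103
21,0.6593808019
22,0.6019802227
23,0.5541313221
24,0.5139271599
25,0.4799
26,0.450907682
27,0.426052386
28,0.4046217603
29,0.3860457184
30,0.3698643646
31,0.3557039251
32,0.3432585051
33,0.3322761312
34,0.3225479806
35,0.3139
36,0.3061863348
37,0.29928414
38,0.2930894539
39,0.2875138969
40,0.2824820133
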