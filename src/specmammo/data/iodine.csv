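# material: iodine (elemental)
# density_g_cm3: 4.93
# k_edge_kev: 33.17
# piecewise power-law fit anchored to mu(25 keV)=68.796 /cm and mu(35 keV)=154.109 /cm
energy_keV,mu_per_cm
15,276.052565
16,231.6080545
17,196.3988522
18,168.119774
19,145.127668
20,126.2287912
21,110.5410358
22,97.40254837
23,86.3098372
24,76.87505402
25,68.796
26,61.83473515
27,55.80210384
28,50.54639259
29,45.9449155
30,41.89770153
31,38.32270925
32,35.15216437
33,32.32973129
33.16,31.90718658
33.18,177.0623913
34,166.1727218
35,154.109
36,143.2248631
37,133.3768435
38,124.4421674
39,116.3153252
40,108.9052811
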