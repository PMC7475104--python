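# Photoelectric linear attenuation coefficient of NaI(Tl),
# density 3.67 g/cm3, iodine K-edge at 33.2 keV.
# Log-log interpolable between the edge discontinuity.
# columns: energy_keV  tau_per_cm
20	114.333
24	66.1651
28	41.6667
31	30.7028
33.1	25.222
33.3	148.621
36	117.627
40	85.75
45	60.225
50	43.904
55	32.9857
60	25.4074
65	19.9836
70	16
75	13.0086
80	10.7188
85	8.93629
90	7.52812
95	6.40093
100	5.488
110	4.12322
120	3.17593
130	2.49795
140	2
150	1.62607
160	1.33984
180	0.941015
200	0.686
220	0.515402
236	0.417521
250	0.351232
260	0.312244
270	0.278819
285	0.237072
300	0.203259
320	0.169656
350	0.132008
380	0.104857
400	0.0908284
450	0.0653123
500	0.0486266
550	0.037237
600	0.0291854
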