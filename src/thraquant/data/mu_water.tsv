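# Narrow-beam linear attenuation coefficient of water, coherent
# scattering excluded (photoelectric + incoherent), density 1.0 g/cm3.
# Log-log interpolable.  columns: energy_keV  mu_per_cm
20.0	0.776593
25.0	0.48849
30.0	0.36192
35.0	0.297107
40.0	0.259951
45.0	0.236676
50.0	0.220998
55.0	0.209775
60.0	0.201315
65.0	0.194656
70.0	0.189217
75.0	0.184637
80.0	0.180682
85.0	0.177195
90.0	0.174067
95.0	0.171223
100.0	0.168608
110.0	0.16391
120.0	0.159752
130.0	0.156001
140.0	0.15257
150.0	0.149402
160.0	0.146454
180.0	0.141102
200.0	0.13634
220.0	0.132052
236.0	0.128908
250.0	0.126338
260.0	0.124596
270.0	0.122924
285.0	0.120539
300.0	0.118287
320.0	0.115473
350.0	0.1116
380.0	0.108088
400.0	0.105919
450.0	0.101005
500.0	0.0966948
550.0	0.0928689
600.0	0.0894394
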