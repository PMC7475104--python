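# Principal photon emissions of the Th-227 decay chain (abundance > 1%).
# Transcribed from the Brookhaven NNDC evaluated data (gamma + x-ray lines).
# columns: nuclide  energy_keV  intensity (photons per decay, fraction)
# group "Th227": Th-227 -> Ra-223 decay only.
# group "Ra223chain": Ra-223 and daughters Rn-219, Pb-211, Bi-211 (Po-215 and
# Tl-207 contribute no photon line above 1%), secular equilibrium assumed.
Th227	12.3	0.210
Th227	50.1	0.080
Th227	79.7	0.017
Th227	85.4	0.012
Th227	88.5	0.020
Th227	94.0	0.014
Th227	210.7	0.011
Th227	236.0	0.123
Th227	256.3	0.070
Th227	286.1	0.015
Th227	300.0	0.023
Th227	304.5	0.012
Th227	329.9	0.027
Th227	334.0	0.011
Ra223	11.7	0.250
Ra223	81.1	0.150
Ra223	83.8	0.249
Ra223	94.9	0.113
Ra223	122.3	0.012
Ra223	144.2	0.032
Ra223	154.2	0.056
Ra223	269.5	0.137
Ra223	323.9	0.039
Ra223	338.3	0.028
Ra223	445.0	0.013
Rn219	11.1	0.011
Rn219	271.2	0.108
Rn219	401.8	0.064
Pb211	404.9	0.038
Pb211	427.1	0.018
Pb211	832.0	0.035
Bi211	10.3	0.011
Bi211	72.9	0.013
Bi211	351.1	0.129
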