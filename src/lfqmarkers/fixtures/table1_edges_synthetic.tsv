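protein_a	protein_b	confidence
Amph	Syp	0.92
Syp	Map2	0.78
Map2	Mapk3	0.71
Amph	Actr3b	0.66
Actr3b	Cap1	0.83
Amph	Ppp3ca	0.58
Ppp3ca	Ppp1cb	0.90
Amph	Dpysl5	0.55
Dpysl5	Crmp1	0.94
Mdh1	Pgk2	0.75
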