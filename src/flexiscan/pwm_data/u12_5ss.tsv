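A	C	G	T
0.01	0.01	0.97	0.01
0.01	0.01	0.01	0.97
0.90	0.03	0.04	0.03
0.03	0.03	0.04	0.90
0.05	0.85	0.05	0.05
0.05	0.85	0.05	0.05
0.06	0.07	0.07	0.80
0.06	0.07	0.07	0.80
0.10	0.12	0.13	0.65
0.40	0.20	0.20	0.20
0.40	0.20	0.20	0.20
0.20	0.40	0.20	0.20
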