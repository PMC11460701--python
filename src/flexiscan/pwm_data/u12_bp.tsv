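A	C	G	T
0.05	0.08	0.07	0.80
0.05	0.08	0.07	0.80
0.06	0.80	0.06	0.08
0.06	0.80	0.06	0.08
0.06	0.08	0.06	0.80
0.06	0.08	0.06	0.80
0.60	0.05	0.30	0.05
0.92	0.03	0.02	0.03
0.08	0.75	0.07	0.10
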