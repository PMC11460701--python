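A	C	G	T
0.05	0.45	0.05	0.45
0.05	0.05	0.05	0.85
0.50	0.05	0.30	0.15
0.92	0.03	0.02	0.03
0.10	0.50	0.05	0.35
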