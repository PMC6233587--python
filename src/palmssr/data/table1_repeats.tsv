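n_repeats	count	percent
5	197	47.13
6	109	26.08
7	48	11.48
8	21	5.02
9	12	2.87
10	2	0.48
11	4	0.96
12	5	1.20
13	1	0.24
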