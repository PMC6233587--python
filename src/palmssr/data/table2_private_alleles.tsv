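marker	allele_size	frequency
Acro2	229	0.059
Acro10	112	0.029
Acro10	115	0.029
Acro14	258	0.059
Acro14	264	0.059
Acro15	106	0.059
Acro29	266	0.529
Acro32	145	0.118
Acro34	339	0.059
Acro36	203	0.300
Acro36	176	0.033
Acro36	185	0.033
Acro36	221	0.033
Acro39	401	0.235
Acro39	350	0.118
Acro41	254	0.029
Acro49	314	0.067
Acro49	386	0.033
Acro52	358	0.118
Acro52	346	0.059
Acro58	422	0.059
Acro62	147	0.423
Acro62	240	0.077
Acro62	246	0.077
Acro63	375	0.063
Acro64	181	0.029
Acro69	400	0.029
Acro82	164	0.059
Acro84	124	0.088
Acro92	409	0.735
Acro93	189	0.059
Acro97	305	0.176
Acro99	262	0.235
Acro101	289	0.706
Acro102	277	0.059
Acro103	384	0.059
Acro108	236	0.059
Acro111	166	0.107
Acro111	169	0.107
Acro111	154	0.071
Acro116	385	0.059
Acro118	324	0.059
Acro118	339	0.059
Acro118	378	0.059
Acro118	358	0.029
Acro125	223	0.059
Acro126	350	0.059
Acro130	283	0.059
Acro136	160	0.059
Acro137	146	0.033
Acro142	393	0.067
Acro143	126	0.059
Acro144	175	0.059
Acro144	211	0.059
Acro146	173	0.088
Acro147	273	0.125
Acro153	348	0.500
Acro153	345	0.346
Acro153	342	0.077
Acro153	306	0.038
Acro153	351	0.038
Acro159	354	0.059
Acro162	136	0.059
Acro164	246	0.059
Acro165	157	0.294
Acro168	233	0.063
Acro168	290	0.063
Acro171	449	0.147
Acro172	252	0.029
Acro178	350	0.029
Acro178	356	0.029
Acro183	383	0.235
Acro183	395	0.059
Acro183	404	0.059
Acro187	201	0.038
Acro188	206	0.059
Acro188	209	0.029
Acro189	277	0.088
Acro189	291	0.059
Acro189	307	0.059
Acro191	243	0.059
Acro192	358	0.059
Acro193	300	0.059
Acro195	397	0.067
Acro196	253	0.063
Acro198	280	0.067
Acro199	349	0.059
Acro199	352	0.059
Acro201	354	0.179
Acro201	342	0.036
Acro201	369	0.036
Acro201	417	0.036
Acro203	215	0.206
Acro203	167	0.118
Acro203	260	0.029
Acro205	120	0.094
Acro205	126	0.063
Acro205	171	0.063
Acro205	180	0.031
Acro205	183	0.031
Acro205	192	0.031
Acro205	195	0.031
Acro206	338	0.250
Acro206	362	0.063
Acro206	365	0.063
Acro206	385	0.063
Acro208	409	0.471
Acro208	418	0.059
Acro209	213	0.529
Acro210	242	0.133
Acro210	278	0.033
Acro212	242	0.176
Acro212	170	0.059
Acro212	113	0.029
Acro212	152	0.029
Acro213	239	0.059
Acro213	236	0.029
Acro217	105	0.059
Acro218	142	0.059
Acro218	109	0.029
Acro223	212	0.059
Acro227	369	0.059
Acro227	390	0.059
Acro228	259	0.265
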