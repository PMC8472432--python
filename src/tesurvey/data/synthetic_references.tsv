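family	superfamily	d1	d2	de3	n_min	n_max	third
Tigger	pogo	135	233	263	29	36	D
Fot	pogo	119	213	248	35	36	D
mariner	Tc1/mariner	130	219	253	34	34	D
maT	Tc1/mariner	126	228	265	37	37	D
GT	Tc1/mariner	112	201	240	39	39	D
VS	Tc1/mariner	138	234	275	40	41	D
Tc1	Tc1/mariner	136	231	265	34	34	E
IC	Tc1/mariner	132	224	260	36	36	E
IT	Tc1/mariner	136	238	276	38	38	E
TR	Tc1/mariner	110	207	242	35	35	E
TRT	Tc1/mariner	137	241	278	37	37	E
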