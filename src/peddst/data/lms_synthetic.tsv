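sex	age_months	L	M	S
male	0	1.0	13.000000	0.18
male	12	1.0	13.628408	0.18
male	24	1.0	14.256816	0.18
male	36	1.0	14.885224	0.18
male	48	1.0	15.513632	0.18
male	60	1.0	16.142040	0.18
male	72	1.0	16.770448	0.18
male	84	1.0	17.398856	0.18
male	96	1.0	18.027264	0.18
male	108	1.0	18.655672	0.18
male	120	1.0	19.284080	0.18
male	132	1.0	19.912488	0.18
male	144	1.0	20.540896	0.18
male	156	1.0	21.169304	0.18
male	168	1.0	21.797711	0.18
male	180	1.0	22.426119	0.18
male	192	1.0	23.054527	0.18
male	204	1.0	23.682935	0.18
male	216	1.0	24.311343	0.18
male	228	1.0	24.939751	0.18
female	0	1.0	13.000000	0.18
female	12	1.0	13.628408	0.18
female	24	1.0	14.256816	0.18
female	36	1.0	14.885224	0.18
female	48	1.0	15.513632	0.18
female	60	1.0	16.142040	0.18
female	72	1.0	16.770448	0.18
female	84	1.0	17.398856	0.18
female	96	1.0	18.027264	0.18
female	108	1.0	18.655672	0.18
female	120	1.0	19.284080	0.18
female	132	1.0	19.912488	0.18
female	144	1.0	20.540896	0.18
female	156	1.0	21.169304	0.18
female	168	1.0	21.797711	0.18
female	180	1.0	22.426119	0.18
female	192	1.0	23.054527	0.18
female	204	1.0	23.682935	0.18
female	216	1.0	24.311343	0.18
female	228	1.0	24.939751	0.18
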