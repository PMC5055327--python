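case_id	age	sex	diagnosis	grade	idh_status	heterogeneity_label	entropy	border_label	edge_mean	edge_median
1	22	F	DA	2	mt	homo	6.17	well defined	33.47	28.64
2	24	M	DA	2	wt	hetero	6.13	vague	27.54	24.08
3	25	M	DA	2	wt	hetero	5.73	well defined	23.64	21.38
4	26	F	DA	2	wt	homo	5.74	well defined	50.28	50.96
5	30	F	DA	2	mt	hetero	6.10	vague	31.89	21.63
6	31	M	DA	2	mt	hetero	6.25	well defined	52.37	42.98
7	40	M	DA	2	mt	homo	5.69	well defined	34.48	29.43
8	42	F	DA	2	wt	homo	5.59	well defined	25.62	21.56
9	42	F	DA	2	mt	hetero	5.82	vague	28.37	22.00
10	46	M	DA	2	mt	homo	5.79	well defined	38.06	35.36
11	49	F	DA	2	wt	homo	5.77	vague	19.35	16.13
12	64	M	DA	2	mt	hetero	7.06	vague	33.09	24.20
13	65	F	DA	2	mt	hetero	5.76	vague	15.98	12.21
14	67	M	DA	2	mt	hetero	5.43	well defined	31.40	24.84
15	44	M	GG	2	wt	homo	6.40	well defined	82.86	73.35
16	33	M	OA	2	mt	homo	6.34	vague	32.94	28.93
17	36	M	OA	2	mt	hetero	5.86	vague	23.93	19.00
18	36	F	OL	2	mt	hetero	5.85	well defined	38.87	26.73
19	38	F	OL	2	wt	homo	6.37	well defined	46.64	38.08
20	39	F	OL	2	mt	hetero	6.79	vague	62.99	56.89
21	40	M	OL	2	mt	homo	6.02	well defined	23.11	19.11
22	44	F	OL	2	mt	hetero	6.29	well defined	37.53	31.13
23	31	F	AA	3	mt	hetero	6.45	vague	30.58	23.35
24	32	M	AA	3	mt	hetero	6.40	vague	23.11	18.00
25	36	F	AA	3	wt	hetero	6.55	vague	21.87	17.89
26	45	M	AA	3	mt	hetero	6.71	vague	46.42	34.89
27	45	M	AA	3	wt	homo	5.12	vague	18.97	16.76
28	46	F	AA	3	mt	hetero	5.39	vague	16.79	13.60
29	62	F	AA	3	wt	hetero	5.74	vague	19.81	16.97
30	62	F	AA	3	wt	hetero	6.20	vague	29.22	20.56
31	68	M	AA	3	mt	hetero	6.20	vague	24.12	17.00
32	70	M	AA	3	wt	hetero	5.72	vague	17.53	14.32
33	71	F	AA	3	wt	hetero	5.70	vague	26.78	21.93
34	75	M	AA	3	wt	hetero	5.41	well defined	26.93	18.44
35	78	M	AA	3	wt	homo	5.06	vague	15.36	12.65
36	79	M	AA	3	wt	homo	5.04	vague	17.59	12.04
37	79	M	AA	3	wt	hetero	5.67	well defined	23.60	19.65
38	38	M	AO	3	wt	hetero	5.88	vague	26.70	19.21
39	19	M	AOA	3	mt	hetero	6.43	well defined	51.18	36.13
40	26	F	AOA	3	mt	hetero	6.92	well defined	60.75	47.52
41	27	M	AOA	3	wt	hetero	7.12	well defined	58.59	40.71
42	29	F	AOA	3	wt	hetero	6.23	well defined	42.86	34.06
43	32	F	AOA	3	wt	hetero	6.25	well defined	31.09	24.00
44	35	M	AOA	3	wt	hetero	6.25	well defined	34.18	28.75
45	39	F	AOA	3	mt	hetero	6.95	well defined	64.04	50.46
46	39	F	AOA	3	mt	hetero	6.31	vague	23.88	18.00
47	41	M	AOA	3	mt	hetero	7.21	well defined	52.28	35.51
48	52	M	AOA	3	mt	hetero	7.14	well defined	42.09	29.43
49	76	M	AOA	3	mt	hetero	6.34	vague	31.47	22.56
50	88	F	AOA	3	mt	hetero	7.01	vague	46.96	39.12
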