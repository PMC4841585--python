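property	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y	X
hydrophobicity	1.8	2.5	-3.5	-3.5	2.8	-0.4	-3.2	4.5	-3.9	3.8	1.9	-3.5	-1.6	-3.5	-4.5	-0.8	-0.7	4.2	-0.9	-1.3	0
solvent_accessibility	115	135	150	190	210	75	195	175	200	170	185	160	145	180	225	115	140	155	255	230	0
polarity	8.1	5.5	13.0	12.3	5.2	9.0	10.4	5.2	11.3	4.9	5.7	11.6	8.0	10.5	10.5	9.2	8.6	5.9	5.4	6.2	0
polarizability	0.046	0.128	0.105	0.151	0.290	0.000	0.230	0.186	0.219	0.186	0.221	0.134	0.131	0.180	0.291	0.062	0.108	0.140	0.409	0.298	0
accessible_surface	0.74	0.91	0.62	0.62	0.88	0.72	0.78	0.88	0.52	0.85	0.85	0.63	0.64	0.62	0.64	0.66	0.70	0.86	0.85	0.76	0
pk_n	9.69	10.28	9.60	9.67	9.13	9.60	9.17	9.60	8.95	9.60	9.21	8.80	10.60	9.13	9.04	9.15	9.10	9.62	9.39	9.11	0
pk_c	2.34	1.96	1.88	2.19	1.83	2.34	1.82	2.36	2.18	2.36	2.28	2.02	1.99	2.17	2.17	2.21	2.09	2.32	2.83	2.20	0
melting_point	297	178	270	249	284	290	277	284	224	337	283	236	222	185	238	228	253	293	282	344	0
molecular_weight	89.09	121.15	133.10	147.13	165.19	75.07	155.16	131.17	146.19	131.17	149.21	132.12	115.13	146.15	174.20	105.09	119.12	117.15	204.24	181.19	0
optical_rotation	1.80	-16.50	5.05	12.00	-34.50	0.00	-38.50	12.40	14.60	-11.00	-10.00	-5.60	-86.20	6.30	12.50	-7.50	-28.00	5.63	-33.70	-10.00	0
net_charge_index	0.007187	-0.036610	-0.023820	0.006802	0.037552	0.179052	-0.010690	0.021631	0.017708	0.051672	0.002683	0.005392	0.239531	0.049211	0.043587	0.004627	0.003352	0.057004	0.037977	0.023599	0
entropy_of_formation	154.33	219.79	194.91	223.16	204.74	127.90	242.54	233.21	300.46	232.30	202.65	207.90	179.93	235.51	341.01	174.06	205.80	207.60	237.01	229.15	0
heat_capacity	29.22	50.70	37.09	41.84	48.52	23.71	59.64	45.00	57.10	48.03	69.32	38.30	36.13	44.02	26.37	32.40	35.20	40.35	56.92	51.73	0
absolute_entropy	30.88	53.83	40.66	44.98	51.06	24.74	65.99	49.71	63.21	50.62	55.32	41.70	39.21	46.62	68.43	35.65	36.50	42.75	60.00	51.15	0
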