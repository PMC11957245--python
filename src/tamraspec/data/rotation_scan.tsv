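group	delta_deg	state	energy_eV	lambda_nm	f	occ_mo	unocc_mo	percent
ref	0	1	2.69	460	0.8695	113	114	98.6
ref	0	2	2.92	424	0.1257	112	114	95.1
Ph	5	1	2.68	462	0.8498	113	114	97.9
Ph	5	2	2.92	424	0.1456	112	114	94.5
Ph	10	1	2.66	466	0.7848	113	114	96.0
Ph	10	2	2.92	425	0.2023	112	114	92.6
Ph	15	1	2.62	474	0.6893	113	114	93.5
Ph	15	2	2.91	427	0.2813	112	114	89.9
Ph	20	1	2.55	486	0.5837	113	114	91.0
Ph	20	2	2.89	429	0.3631	112	114	87.2
Ph	25	1	2.47	502	0.4839	113	114	89.2
Ph	25	2	2.88	431	0.4329	112	114	84.9
Ph	30	1	2.37	523	0.4004	113	114	88.2
Ph	30	2	2.86	433	0.4819	112	114	83.5
COO	15	1	2.65	467	0.7715	113	114	92.7
COO	15	2	2.83	438	0.1788	112	114	88.5
COO	30	1	2.56	484	0.3733	113	114	58.1
COO	30	2	2.71	457	0.5327	112	114	57.5
COO	45	1	2.47	501	0.1101	112	114	73.2
COO	45	2	2.65	468	0.7761	113	114	73.2
COO	60	1	2.43	511	0.0308	112	114	90.1
COO	60	2	2.61	474	0.8521	113	114	89.5
COO	75	1	2.40	516	0.0094	112	114	96.6
COO	75	2	2.60	477	0.8769	113	114	95.9
COO	90	1	2.40	517	0.0072	112	114	97.5
COO	90	2	2.59	478	0.8778	113	114	96.7
NMe2	15	1	2.68	463	0.8670	113	114	98.6
NMe2	15	2	2.91	426	0.1267	112	114	94.8
NMe2	30	1	2.63	471	0.8496	113	114	98.8
NMe2	30	2	2.88	431	0.1306	112	114	93.8
NMe2	45	1	2.55	486	0.7784	113	114	98.9
NMe2	45	2	2.81	440	0.1442	112	114	92.1
NMe2	60	1	2.38	522	0.5290	113	114	97.1
NMe2	60	2	2.73	454	0.2044	112	114	88.8
NMe2	75	1	2.04	608	0.1501	113	114	96.3
NMe2	75	2	2.66	467	0.3026	112	114	84.8
NMe2	90	1	1.80	691	0	113	114	98.1
NMe2	90	2	2.63	472	0.3312	112	114	82.8
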