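basis	dispersion	state	energy_eV	lambda_nm	f	occ_mo	unocc_mo	percent
6-31+G(d)	D3BJ	1	2.71	458	0.8659	113	114	98.6
6-31+G(d)	D3BJ	2	2.98	416	0.1413	112	114	94.6
6-311+G(d,p)	none	1	2.70	460	0.8733	113	114	98.5
6-311+G(d,p)	none	2	2.93	423	0.1296	112	114	95.3
6-311+G(d,p)	D3BJ	1	2.71	457	0.8705	113	114	98.5
6-311+G(d,p)	D3BJ	2	2.98	416	0.1392	112	114	95.1
6-311G(d,p)	none	1	2.72	456	0.0013	112	114	99.4
6-311G(d,p)	none	2	2.75	451	0.7715	113	114	96.3
6-311G(d,p)	none	3	2.88	431	0.1131	111	114	65.0
6-311G(d,p)	D3BJ	1	2.62	474	0.0014	113	114	99.3
6-311G(d,p)	D3BJ	2	2.71	458	0.1014	111	114	85.3
6-311G(d,p)	D3BJ	3	2.73	454	0.7474	112	114	92.8
aug-cc-pVDZ	none	1	2.68	463	0.8668	113	114	98.5
aug-cc-pVDZ	none	2	2.92	425	0.1295	112	114	95.3
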