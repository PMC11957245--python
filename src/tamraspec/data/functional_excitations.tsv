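functional	state	energy_eV	lambda_nm	f	occ_mo	unocc_mo	percent	character
BP86	1	1.73	718	0.0055	113	114	99.9	CT
BP86	2	2.13	581	0.0016	110	114	94.9	CT
BP86	3	2.17	571	0.0508	111	114	73.0	CT
BP86	4	2.38	521	0.6351	112	114	95.2	pi-pi*
BLYP	1	1.70	730	0.0054	113	114	99.9	CT
BLYP	2	2.04	607	0.0340	111	114	75.3	CT
BLYP	3	2.13	582	0.0208	110	114	82.8	CT
BLYP	4	2.35	527	0.6099	112	114	91.2	pi-pi*
TPSS	1	1.88	659	0.0048	113	114	99.9	CT
TPSS	2	2.27	547	0.0016	110	114	98.7	CT
TPSS	3	2.30	538	0.0554	111	114	75.8	CT
TPSS	4	2.47	502	0.6713	112	114	95.7	pi-pi*
B3LYP	1	2.69	461	0.8692	113	114	98.6	pi-pi*
B3LYP	2	2.92	424	0.1259	112	114	95.1	pCT
PBE0	1	2.79	445	0.8993	113	114	98.5	pi-pi*
PBE0	2	3.15	393	0.1809	112	114	95.2	pCT
TPSSh	1	2.54	489	0.0028	112	114	99.6	pi-pi*
TPSSh	2	2.63	471	0.7810	113	114	97.9	CT
M06-2X	1	2.91	426	1.0537	113	114	97.1	pi-pi*
M06-2X	2	3.74	332	0.0598	112	114	77.4	pi-pi*
M06-2X	3	3.91	317	0.1513	111	114	73.1	pCT
CAM-B3LYP	1	2.97	417	1.0384	113	114	96.3	pi-pi*
CAM-B3LYP	2	3.74	332	0.1898	112	114	90.4	pCT
wB97XD	1	3.00	413	1.0368	113	114	95.1	pi-pi*
wB97XD	2	3.73	332	0.2229	112	114	84.4	pCT
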