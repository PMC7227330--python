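code	abbrev	name	n_use_reports	pct_use_reports	n_species	pct_species	category_uv	icf
1	BVP	Diseases caused by bacterial, viral, and parasitic infections	3588	8.70	61	9.49	3.04	0.98
2	TGP	Tissue growth problems	991	2.40	18	2.80	0.95	0.98
3	ENM	Endocrine, nutritional, and metabolic	1367	3.31	36	5.60	1.03	0.97
4	DNS	Diseases of the nervous system	239	0.58	7	1.09	0.19	0.97
5	EYE	Diseases of the eye	308	0.75	8	1.24	0.25	0.98
6	EAR	Diseases of the ear	410	0.99	8	1.24	0.36	0.98
7	DCS	Diseases of the circulatory system	1333	3.23	31	4.82	0.92	0.98
8	DRS	Diseases of the respiratory system	3896	9.44	67	10.42	2.66	0.98
9	DDS	Diseases of the digestive system	6322	15.33	82	12.75	4.64	0.99
10	DOS	Diseases of the skin	2563	6.21	40	6.22	2.10	0.99
11	MCP	Musculoskeletal system and connective tissue problems	2597	6.30	42	6.53	2.23	0.98
12	GUP	Genito-urinary problems	2358	5.72	39	6.07	1.72	0.98
13	PMI	Uses in pregnancy to delivery, maternal and infant care	1914	4.64	40	6.22	1.25	0.98
14	ASS	Abnormal signs and symptoms	8133	19.72	88	13.69	5.84	0.99
15	OEC	Other problems of external causes	5023	12.18	70	10.89	3.98	0.99
16	OTU	Other uses	205	0.50	6	0.93	0.27	0.98
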