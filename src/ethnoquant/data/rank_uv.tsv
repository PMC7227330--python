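rank	scientific_name	uv	civ	ud
1	Anodendron borneense	3.39	3.68	2.22
2	Piper decumanum	3.04	3.45	2.06
3	Micromelum minutum	2.85	3.28	2.03
4	Arcangelisia flava	2.75	3.23	2.14
5	Cinnamomum mercadoi	2.71	3.22	1.93
6	Piper nigrum	2.46	2.41	1.20
7	Jatropha gossypifolia	2.41	2.83	1.94
8	Tinospora crispa	2.33	2.68	1.95
9	Sida rhombifolia	2.29	2.55	1.87
10	Hellenia speciosa	2.22	2.58	2.03
11	Premna odorata	1.99	2.94	1.79
12	Carica papaya	1.97	2.92	1.64
13	Ficus concinna	1.81	2.66	1.37
14	Rhinacanthus nasutus	1.74	2.90	1.74
15	Ficus septica	1.72	2.13	1.77
16	Stenomeris borneensis	1.61	2.36	1.70
17	Pipturus arborescens	1.61	2.25	1.58
18	Ormosia macrodisca	1.56	2.36	1.56
19	Orthosiphon aristatus	1.53	2.96	1.58
20	Pseudelephantopus spicatus	1.49	2.50	1.44
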