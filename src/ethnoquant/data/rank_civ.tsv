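rank	scientific_name	civ	uv	ud
1	Anodendron borneense	3.68	3.39	2.22
2	Piper decumanum	3.45	3.04	2.06
3	Micromelum minutum	3.28	2.85	2.03
4	Arcangelisia flava	3.23	2.75	2.14
5	Cinnamomum mercadoi	3.22	2.71	1.93
6	Andrographis paniculata	3.07	1.43	2.09
7	Eleusine indica	3.04	1.44	2.34
8	Ficus cassidyana	3.00	1.47	1.89
9	Orthosiphon aristatus	2.96	1.53	1.58
10	Premna odorata	2.94	1.99	1.79
11	Carica papaya	2.92	1.97	1.64
12	Rhinacanthus nasutus	2.90	1.74	1.74
13	Kalanchoe pinnata	2.88	1.45	2.21
14	Mangifera indica	2.85	0.66	1.47
15	Litsea cordata	2.83	0.92	1.79
16	Jatropha gossypifolia	2.83	2.41	1.94
17	Mentha canadensis	2.81	1.29	2.04
18	Euphorbia hirta	2.80	0.91	1.85
19	Cyanthillium cinereum	2.78	1.42	1.42
20	Mikania cordata	2.75	1.19	1.67
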