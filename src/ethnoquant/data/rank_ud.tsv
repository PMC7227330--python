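rank	scientific_name	ud	uv	civ
1	Eleusine indica	2.34	1.44	3.04
2	Anodendron borneense	2.22	3.39	3.68
3	Kalanchoe pinnata	2.21	1.45	2.88
4	Swietenia mahagoni	2.14	1.00	2.29
5	Arcangelisia flava	2.14	2.75	3.23
6	Andrographis paniculata	2.09	1.43	3.07
7	Ocimum basilicum	2.09	1.15	2.33
8	Piper decumanum	2.06	3.04	3.45
9	Amaranthus spinosus	2.06	0.63	2.75
10	Mentha canadensis	2.04	1.29	2.81
11	Alstonia macrophylla	2.04	1.15	2.71
12	Micromelum minutum	2.03	2.85	3.28
13	Hellenia speciosa	2.03	2.22	2.58
14	Annona muricata	2.02	0.62	2.17
15	Phyllanthus amarus	2.01	1.37	2.35
16	Abroma augusta	1.98	0.98	2.69
17	Mimosa pudica	1.97	1.06	2.29
18	Tinospora crispa	1.95	2.33	2.68
19	Jatropha gossypifolia	1.94	2.41	2.83
20	Cinnamomum mercadoi	1.93	2.71	3.22
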