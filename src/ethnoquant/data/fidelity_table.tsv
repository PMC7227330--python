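rank	scientific_name	ailment	ip	iu	fl
1	Carica papaya	Dengue fever	158	158	100
2	Premna odorata	Cough with phlegm	238	238	100
3	Cinnamomum mercadoi	Stomach trouble	223	223	100
4	Tinospora crispa	Joint pain	157	157	100
5	Ficus concinna	Fracture and dislocation	41	41	100
6	Piper decumanum	Anesthetic	68	68	100
7	Pipturus arborescens	Herpes simplex	59	59	100
8	Rhinacanthus nasutus	Nervous breakdown	44	45	98
9	Stenomeris borneensis	Urinary bladder swelling	133	136	98
10	Micromelum minutum	Hemorrhage	70	72	97
11	Piper nigrum	Skin rashes and itchiness	203	214	95
12	Jatropha gossypifolia	Discharging ear	59	63	94
13	Orthosiphon aristatus	Diabetes	68	72	94
14	Ormosia macrodisca	Atherosclerosis	63	69	91
15	Sida rhombifolia	Cramp and spasm	71	79	90
16	Pseudelephantopus spicatus	Urinary tract infection	85	95	89
17	Anodendron borneense	Pregnancy	38	43	88
18	Arcangelisia flava	Tumor	73	84	87
19	Hellenia speciosa	Goiter	44	52	85
20	Ficus septica	Eye problem	32	39	82
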