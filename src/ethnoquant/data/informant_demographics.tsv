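variable	level	n_informants
location	Bayugan City	150
location	Sibagat	90
location	Esperanza	95
education	Primary	57
education	Secondary	167
education	Higher education	111
gender	Male	229
gender	Female	106
social_position	Tribal chieftain	45
social_position	Tribal healer	3
social_position	Tribal IPMR	6
social_position	Tribal leader	31
social_position	NCIP focal person	4
social_position	Council of elders	7
social_position	Member	239
occupation	Farming	205
occupation	Animal husbandry	47
occupation	Employed	49
occupation	Unemployed	16
occupation	Others	18
civil_status	Single	187
civil_status	Married	133
civil_status	Others	15
age_group	18-34	142
age_group	35-49	103
age_group	50-65	53
age_group	>65	37
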