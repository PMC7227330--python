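marker	primer_name	direction	sequence
ITS	p17	F	CTACCGATTGAATGGTCCGGTGAA
ITS	26S-82	R	TCCCGGTTCGCTCGCCGTTACTA
ITS	5	F	GGAAGTAAAAGTCGTAACAAGG
ITS	4	R	TCCTCCGCTTATTGATATGC
matK	3F_kim	F	CGTACAGTACTTTTGTGTTTACGAG
matK	1R_kim	R	ACCCAGTCCATCTGGAAATCTTGGTTC
psbA-trnH	psbA_F	F	GTTATGCATGAACGTAATGCTC
psbA-trnH	trnH_R	R	CGCGCATGGTGGATTCACAATCC
trnL-F	c	F	CGAAATCGGTAGACGCTACG
trnL-F	f	R	ATTTGAACTGGTGACACGAG
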