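var_a	var_b	rho
UR	UC	0.74
UR	UV	1.00
UR	CIV	0.73
UR	UD	0.71
UC	UV	0.74
UC	CIV	0.71
UC	UD	0.97
UV	CIV	0.73
UV	UD	0.71
CIV	UD	0.69
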