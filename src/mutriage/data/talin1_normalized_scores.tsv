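# Externally normalized substitution penalties for the bundled catalog
# (fixture scheme; one row per unique substitution and matrix).
wt	mut	matrix	value
P	L	BLOSUM62	1
I	N	BLOSUM62	1
V	D	BLOSUM62	1
A	E	BLOSUM62	0.75
R	W	BLOSUM62	1
Y	C	BLOSUM62	0.87
L	P	BLOSUM62	1
S	F	BLOSUM62	0.87
E	Q	BLOSUM62	0.37
D	V	BLOSUM62	1
P	L	CBSM60	1
I	N	CBSM60	0.83
V	D	CBSM60	1
A	E	CBSM60	0.33
R	W	CBSM60	1
Y	C	CBSM60	0.67
L	P	CBSM60	1
S	F	CBSM60	0.5
E	Q	CBSM60	-0.33
D	V	CBSM60	1
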