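mutation	final_score
P229L	8.20
I392N	8.95
V577D	8.39
A893E	7.63
R1368W	7.75
Y1389C	8.58
L1539P	8.45
S1750F	7.55
E1770Q	6.01
D2086V	7.71
L2509P	7.46
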