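mutation	probability
P229L	0.94
I392N	0.86
V577D	0.94
A893E	0.95
R1368W	0.98
Y1389C	0.90
L1539P	0.98
S1750F	0.89
E1770Q	0.81
D2086V	0.96
L2509P	0.96
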