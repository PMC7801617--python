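# Normalized conservation at the bundled catalog positions (fixture mode).
position	score
229	1
392	1
577	0.60
893	0.60
1368	1
1389	1
1539	0.60
1750	0.60
1770	1
2086	1
2509	0.64
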