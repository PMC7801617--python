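# Explicit per-residue structural environment for the bundled catalog
# positions (authoritative table mode; bh = between helices).
position	location_class	bh
229	buried	1
392	buried	0
577	buried	0
893	buried	1
1368	surface	0
1389	buried	0
1539	buried	0
1750	buried	0
1770	surface	0
2086	surface	0
2509	surface	0
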