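bit	value	label
1	1	CLIMAP
2	2	BUFD
3	4	ATL947
4	8	MARGO North Atlantic
5	16	MARGO South Atlantic
6	32	MARGO Indo-Pacific
7	64	MARGO Pacific
8	128	MARGO Mediterranean
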