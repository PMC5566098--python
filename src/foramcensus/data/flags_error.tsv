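bit	value	label
1	1	modified
2	2	outlier
3	4	dissolution affected
4	8	duplicate
5	16	taxonomically incorrect
6	32	too many unidentified
7	64	sum deviates
8	128	too few counted
9	256	non-standard sampling device
10	512	no geographical coordinates
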