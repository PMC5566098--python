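bit	value	label
1	1	All oceans
2	2	Atlantic
3	4	North Atlantic
4	8	South Atlantic
5	16	Pacific
6	32	North Pacific
7	64	South Pacific
8	128	Indian Ocean
9	256	Southern Ocean
10	512	Arctic Ocean
11	1024	Mediterranean Sea
12	2048	Red Sea
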