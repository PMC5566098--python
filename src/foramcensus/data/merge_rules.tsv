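source_kind	source	target	datasets	rationale
label	Globigerina pachyderma	pd_intergrades	CLIMAP	undifferentiated pachyderma category used for pachyderma/dutertrei intergrades
code	pd_intergrades	n_incompta	CLIMAP,ATL947,MARGO,Munz	intergrade morphologies belong to N. incompta
code	g_flexuosa	g_menardii	CLIMAP,BUFD	flexuosa morphotype is not a separate species
code	g_crassula	unidentified	BUFD,MARGO	extinct species, no unambiguous extant assignment
code	other_identified	unidentified	BUFD,MARGO	residual category cannot be resolved
code	g_puncticulata	g_inflata	Munz	extinct species overlapping its descendant G. inflata
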