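synonym	code	source
Globigerina digitata	b_digitata	table2
Globigerinella digitata	b_digitata	table2
Globigerinita pumilio	b_pumilio	table2
Dentagloborotalia anfracta	d_anfracta	table2
Globorotalia anfracta	d_anfracta	table2
Globigerina calida	g_calida	table2
Globigerinella aequilateralis	g_siphonifera	table2
Globigerinita bradyi	g_uvula	table2
Globoturborotalita tenella	g_tenellus	table2
Globorotalia inflata	g_inflata	table2
Globorotalia menardii flexuosa	g_menardii	table2
Globorotalia tumida flexuosa	g_tumida	table2
Globoquadrina hexagona	g_hexagonus	table2
Globigerina rubescens	g_rubescens	table2
Hastigerina digitata	h_digitata	table2
Globigerina pachyderma	n_pachyderma	table2
Neogloboquadrina pachyderma sinistral	n_pachyderma	table2
Globoquadrina dutertrei	n_dutertrei	table2
Neogloboquadrina pachyderma dextral	n_incompta	table2
Globigerinita iota	t_iota	table2
Globigerinoides sacculifer	t_sacculifer	table2
Globigerinoides trilobus	t_sacculifer	table2
Globigerina humilis	t_humilis	table2
Turborotalia cristata	t_humilis	table2
Turborotalia humilis	t_humilis	table2
Globigerina quinqueloba	t_quinqueloba	table2
Turborotalia quinqueloba	t_quinqueloba	table2
Globigerinoides ruber	ruber_pink_white	extra
Neogloboquadrina pachyderma d	n_incompta	extra
Neogloboquadrina pachyderma s	n_pachyderma	extra
PD intergrades	pd_intergrades	extra
Globigerinoides flexuosa	g_flexuosa	extra
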