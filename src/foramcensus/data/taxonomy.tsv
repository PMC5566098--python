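code	kind	genus	species	parent	recorded
d_anfracta	species	Dentigloborotalia	anfracta		1
g_cavernula	species	Globorotalia	cavernula		1
g_crassaformis	species	Globorotalia	crassaformis		1
g_hirsuta	species	Globorotalia	hirsuta		1
g_menardii	species	Globorotalia	menardii		1
g_scitula	species	Globorotalia	scitula		1
g_truncatulinoides	species	Globorotalia	truncatulinoides		1
g_tumida	species	Globorotalia	tumida		1
g_ungulata	species	Globorotalia	ungulata		1
g_theyeri	species	Globorotalia	theyeri		1
g_inflata	species	Globoconella	inflata		1
n_dutertrei	species	Neogloboquadrina	dutertrei		1
n_incompta	species	Neogloboquadrina	incompta		1
n_pachyderma	species	Neogloboquadrina	pachyderma		1
p_obliquiloculata	species	Pulleniatina	obliquiloculata		1
g_conglomerata	species	Globoquadrina	conglomerata		1
g_hexagonus	species	Globorotaloides	hexagonus		1
b_pumilio	species	Berggrenia	pumilio		1
g_bulloides	species	Globigerina	bulloides		1
g_falconensis	species	Globigerina	falconensis		1
g_conglobatus	species	Globigerinoides	conglobatus		1
g_ruber_pink	species	Globigerinoides	ruber (pink)		1
g_ruber_white	species	Globigerinoides	ruber (white)		1
t_sacculifer	species	Trilobatus	sacculifer		1
g_tenellus	species	Globigerinoides	tenellus		1
o_universa	species	Orbulina	universa		1
b_digitata	species	Beella	digitata		1
g_siphonifera	species	Globigerinella	siphonifera		1
g_calida	species	Globigerinella	calida		1
g_adamsi	species	Globigerinella	adamsi		1
t_quinqueloba	species	Turborotalita	quinqueloba		1
t_humilis	species	Turborotalita	humilis		1
g_rubescens	species	Globoturborotalita	rubescens		1
s_dehiscens	species	Sphaeroidinella	dehiscens		1
c_nitida	species	Candeina	nitida		1
g_glutinata	species	Globigerinita	glutinata		1
g_uvula	species	Globigerinita	uvula		1
g_minuta	species	Globigerinita	minuta		1
t_iota	species	Tenuitella	iota		1
h_pelagica	species	Hastigerina	pelagica		1
h_digitata	species	Hastigerinella	digitata		1
g_elongatus	species	Globorotaloides	elongatus		0
g_radians	species	Globigerinella	radians		0
o_riedeli	species	Orcadia	riedeli		0
t_clarkei	species	Turborotalita	clarkei		0
t_fleisheri	species	Tenuitella	fleisheri		0
t_parkerae	species	Tenuitella	parkerae		0
menardii_tumida	multi_species	Globorotalia	menardii & tumida		1
ruber_pink_white	multi_species	Globigerinoides	ruber (pink & white)		1
humilis_pumilio	multi_species	Turborotalita	humilis & Berggrenia pumilio		1
t_sacculifer_sac	morphotype	Trilobatus	sacculifer with sac-like chamber	t_sacculifer	1
t_sacculifer_nosac	morphotype	Trilobatus	sacculifer without sac-like chamber	t_sacculifer	1
g_truncatulinoides_d	morphotype	Globorotalia	truncatulinoides dextral coiling	g_truncatulinoides	1
g_truncatulinoides_s	morphotype	Globorotalia	truncatulinoides sinistral coiling	g_truncatulinoides	1
t_quinqueloba_d	morphotype	Turborotalita	quinqueloba dextral coiling	t_quinqueloba	1
t_quinqueloba_s	morphotype	Turborotalita	quinqueloba sinistral coiling	t_quinqueloba	1
unidentified	special		unidentified		1
pd_intergrades	legacy		P/D intergrades		1
g_flexuosa	legacy	Globorotalia	flexuosa		1
g_crassula	legacy	Globorotalia	crassula		1
other_identified	legacy		other identified		1
g_puncticulata	legacy	Globorotalia	puncticulata		1
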