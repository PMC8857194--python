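herb_id	compound_id
he_shou_wu	polygodial
dang_gui	1,2-benzenedicarboxylic acid
dang_gui	1-methyl-2-dodecyl-4-(1h)-quinolone
dang_gui	4-ethylresorcinol
dang_gui	angelicin
dang_gui	azelaic acid
dang_gui	carvacrol
dang_gui	carvacrol acetate
dang_gui	choline
dang_gui	decanoic acid
dang_gui	dihydropinosylvin
dang_gui	dimethyl phthalate
dang_gui	dodecenoic acid
dang_gui	hexadecanoic acid
dang_gui	m-cresol
dang_gui	m-ethylphenol
dang_gui	o-cresol
dang_gui	p-cresol
dang_gui	p-ethylphenol
dang_gui	phenylacetic acid
dang_gui	sebiferic acid
dang_gui	uridine
shu_di_huang	uridine
chuan_xiong	13-methyl pentadecanoic acid
chuan_xiong	choline
chuan_xiong	dibutyl phthalate
chuan_xiong	hexadecanoic acid
chuan_xiong	linoleic acid
chuan_xiong	methyl pentadecanoate
chuan_xiong	methyl phenylacetate
chuan_xiong	n-butyl-2-ethylbutylphthalate
chuan_xiong	o-cresol
chuan_xiong	o-ethylphenol
chuan_xiong	oleic acid
chuan_xiong	pentadecanoic acid
chuan_xiong	thymol
mo_han_lian	nicotine
mo_han_lian	nicotinic acid
gou_qi_zi	ascorbic acid
gou_qi_zi	nicotinic acid
gou_qi_zi	riboflavin
gou_qi_zi	safranal
gou_qi_zi	vitamin b2
sheng_di_huang	adenosine
sheng_di_huang	uridine
huang_qi	choline
huang_qi	uridine
bai_shao	gallic acid
dan_shen	dauricine
dan_shen	dehydromiltirone
dan_shen	dihydrokaranone
dan_shen	ferruginol
dan_shen	miltionone i
dan_shen	miltirone
dan_shen	neocryptotanshinone ii
dan_shen	neotanshinone c
dan_shen	tanshiquinone b
sang_shen	linoleic acid
sang_shen	myoinositol
sang_shen	oleic acid
sang_shen	trigonelline
sang_shen	vitamin b2
hei_zhi_ma	vitamin e
ce_bai_ye	diethyl phthalate
ce_bai_ye	geranylacetone
ce_bai_ye	isopimaric acid
ce_bai_ye	juniperic acid
ce_bai_ye	verbenone
tian_ma	citronellal
tian_ma	dauricine
tian_ma	m-hydroxybenzoic acid
hong_hua	arachidic acid
hong_hua	carvacrol
hong_hua	safranal
dang_shen	13-methyl pentadecanoic acid
dang_shen	2,4-nonadienal
dang_shen	alpha-curcumene
dang_shen	azelaic acid
dang_shen	caprylic acid
dang_shen	choline
dang_shen	coelogin
dang_shen	heneicosanic acid
dang_shen	methyl pentadecanoate
dang_shen	nicotine
dang_shen	nicotinic acid
dang_shen	nona-2,4-dienal
dang_shen	nonadecanoic acid
dang_shen	octadecanoic acid
dang_shen	pentadecanoic acid
dang_shen	phenylic acid
dang_shen	stearic acid
dang_shen	stigmasta-5,22-dien-3-one
dang_shen	taraxerone
mu_gua	2-hexenal
mu_gua	azelaic acid
mu_gua	diethyl phthalate
mu_gua	dodecanoic acid
mu_gua	fumaric acid
mu_gua	linoleic acid
mu_gua	oleic acid
mu_gua	p-hydroxybenzoic acid
mu_gua	palmitoleic acid
mu_gua	phenylacetic acid
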