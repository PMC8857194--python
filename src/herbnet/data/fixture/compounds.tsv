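compound_id	name	ob	dl	prescreened
1,2-benzenedicarboxylic acid	1,2-benzenedicarboxylic acid			true
1-methyl-2-dodecyl-4-(1h)-quinolone	1-methyl-2-dodecyl-4-(1h)-quinolone			true
13-methyl pentadecanoic acid	13-methyl pentadecanoic acid			true
2,4-nonadienal	2,4-nonadienal			true
2-hexenal	2-hexenal			true
4-ethylresorcinol	4-ethylresorcinol			true
adenosine	adenosine			true
alpha-curcumene	alpha-curcumene			true
angelicin	angelicin			true
arachidic acid	arachidic acid			true
ascorbic acid	ascorbic acid			true
azelaic acid	azelaic acid			true
caprylic acid	caprylic acid			true
carvacrol	carvacrol			true
carvacrol acetate	carvacrol acetate			true
choline	choline			true
citronellal	citronellal			true
coelogin	coelogin			true
dauricine	dauricine			true
decanoic acid	decanoic acid			true
dehydromiltirone	dehydromiltirone			true
dibutyl phthalate	dibutyl phthalate			true
diethyl phthalate	diethyl phthalate			true
dihydrokaranone	dihydrokaranone			true
dihydropinosylvin	dihydropinosylvin			true
dimethyl phthalate	dimethyl phthalate			true
dodecanoic acid	dodecanoic acid			true
dodecenoic acid	dodecenoic acid			true
ferruginol	ferruginol			true
fumaric acid	fumaric acid			true
gallic acid	gallic acid			true
geranylacetone	geranylacetone			true
heneicosanic acid	heneicosanic acid			true
hexadecanoic acid	hexadecanoic acid			true
isopimaric acid	isopimaric acid			true
juniperic acid	juniperic acid			true
linoleic acid	linoleic acid			true
m-cresol	m-cresol			true
m-ethylphenol	m-ethylphenol			true
m-hydroxybenzoic acid	m-hydroxybenzoic acid			true
methyl pentadecanoate	methyl pentadecanoate			true
methyl phenylacetate	methyl phenylacetate			true
miltionone i	miltionone i			true
miltirone	miltirone			true
myoinositol	myoinositol			true
n-butyl-2-ethylbutylphthalate	n-butyl-2-ethylbutylphthalate			true
neocryptotanshinone ii	neocryptotanshinone ii			true
neotanshinone c	neotanshinone c			true
nicotine	nicotine			true
nicotinic acid	nicotinic acid			true
nona-2,4-dienal	nona-2,4-dienal			true
nonadecanoic acid	nonadecanoic acid			true
o-cresol	o-cresol			true
o-ethylphenol	o-ethylphenol			true
octadecanoic acid	octadecanoic acid			true
oleic acid	oleic acid			true
p-cresol	p-cresol			true
p-ethylphenol	p-ethylphenol			true
p-hydroxybenzoic acid	p-hydroxybenzoic acid			true
palmitoleic acid	palmitoleic acid			true
pentadecanoic acid	pentadecanoic acid			true
phenylacetic acid	phenylacetic acid			true
phenylic acid	phenylic acid			true
polygodial	polygodial			true
riboflavin	riboflavin			true
safranal	safranal			true
sebiferic acid	sebiferic acid			true
stearic acid	stearic acid			true
stigmasta-5,22-dien-3-one	stigmasta-5,22-dien-3-one			true
tanshiquinone b	tanshiquinone b			true
taraxerone	taraxerone			true
thymol	thymol			true
trigonelline	trigonelline			true
uridine	uridine			true
verbenone	verbenone			true
vitamin b2	vitamin b2			true
vitamin e	vitamin e			true
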