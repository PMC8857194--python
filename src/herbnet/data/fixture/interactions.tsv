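compound_id	target_id	score
1,2-benzenedicarboxylic acid	23475	
1,2-benzenedicarboxylic acid	4837	
1-methyl-2-dodecyl-4-(1h)-quinolone	1601	
13-methyl pentadecanoic acid	5319	
2,4-nonadienal	43	
2-hexenal	43	
4-ethylresorcinol	43	
adenosine	4860	
alpha-curcumene	409	
alpha-curcumene	4860	
alpha-curcumene	7879	
angelicin	156	
angelicin	157	
angelicin	22978	
arachidic acid	5319	
ascorbic acid	2350	
ascorbic acid	2352	
azelaic acid	5319	
caprylic acid	5319	
carvacrol	43	
carvacrol acetate	43	
choline	162466	
choline	43	
choline	5130	
choline	5337	
choline	5338	
choline	9468	
citronellal	43	
coelogin	1606	
dauricine	43	
decanoic acid	5319	
dehydromiltirone	1601	
dibutyl phthalate	43	
diethyl phthalate	43	
dihydrokaranone	4907	
dihydropinosylvin	43	
dimethyl phthalate	43	
dodecanoic acid	5319	
dodecenoic acid	79888	
ferruginol	43	
fumaric acid	79888	
gallic acid	1606	
geranylacetone	4907	
heneicosanic acid	5319	
hexadecanoic acid	5319	
isopimaric acid	79888	
juniperic acid	5319	
linoleic acid	79888	
m-cresol	43	
m-ethylphenol	43	
m-hydroxybenzoic acid	30814	
methyl pentadecanoate	5319	
methyl phenylacetate	43	
miltionone i	2263	
miltirone	1601	
myoinositol	162466	
myoinositol	43	
myoinositol	5130	
myoinositol	5337	
myoinositol	5338	
myoinositol	9468	
n-butyl-2-ethylbutylphthalate	43	
neocryptotanshinone ii	2263	
neotanshinone c	2263	
nicotine	1103	
nicotinic acid	23475	
nicotinic acid	4837	
nona-2,4-dienal	43	
nonadecanoic acid	5319	
o-cresol	43	
o-ethylphenol	43	
octadecanoic acid	5319	
oleic acid	79888	
p-cresol	43	
p-ethylphenol	43	
p-hydroxybenzoic acid	30814	
palmitoleic acid	79888	
pentadecanoic acid	5319	
phenylacetic acid	23475	
phenylacetic acid	4837	
phenylic acid	43	
polygodial	43	
riboflavin	2350	
riboflavin	2352	
safranal	43	
sebiferic acid	79888	
stearic acid	5319	
stigmasta-5,22-dien-3-one	4907	
tanshiquinone b	2263	
taraxerone	4907	
thymol	43	
trigonelline	23475	
trigonelline	4837	
uridine	22978	
uridine	5167	
verbenone	4907	
vitamin b2	2350	
vitamin b2	2352	
vitamin e	2350	
vitamin e	2352	
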