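herb_id	latin_name	pinyin_name
he_shou_wu	Polygonum multiflorum Thunb.	HE SHOU WU
dang_gui	Angelica sinensis (Oliv.) Diels	DANG GUI (CHAO XIAN DANG GUI)
shu_di_huang	Rehmannia glutinosa Libosch. (prepared)	SHU DI HUANG
chuan_xiong	Ligusticum chuanxiong Hort.	CHUAN XIONG
nu_zhen_zi	Ligustrum lucidum Ait.	NU ZHEN ZI
mo_han_lian	Eclipta prostrata L.	MO HAN LIAN
gou_qi_zi	Lycium barbarum L.	GOU QI ZI
sheng_di_huang	Rehmannia glutinosa Libosch.	SHENG DI HUANG
tu_si_zi	Cuscuta chinensis Lam.	TU SI ZI
huang_qi	Astragalus membranaceus (Fisch.) Bge.	HUANG QI
bai_shao	Paeonia lactiflora Pall.	BAI SHAO
dan_shen	Salvia miltiorrhiza Bge.	DAN SHEN
sang_shen	Morus alba L.	SANG SHEN
hei_zhi_ma	Sesamum indicum L.	HEI ZHI MA
ce_bai_ye	Platycladus orientalis (L.) Franco	CE BAI YE
tian_ma	Gastrodia elata Bl.	TIAN MA
hong_hua	Carthamus tinctorius L.	HONG HUA
dang_shen	Codonopsis pilosula (Franch.) Nannf.	DANG SHEN
mu_gua	Chaenomeles speciosa (Sweet) Nakai	MU GUA
huang_jing	Polygonatum sibiricum Red.	HUANG JING
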