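target_id	description
43	Acetylcholinesterase (AChE) (Cartwright blood group)
5319	Phospholipase A2 group IB (PLA2G1B)
79888	Lysophosphatidylcholine acyltransferase 1 (LPCAT1)
4907	Ecto-5'-nucleotidase (NTE5)
2263	Fibroblast growth factor receptor 2 (FGF-2)
2350	Folate receptor beta (FR-beta)
2352	Folate receptor gamma (FR-gamma)
4837	Nicotinamide N-methyltransferase (NNMT)
23475	Quinolinate phosphoribosyltransferase (QPRT)
1601	DAB adaptor protein 2
1606	Diacylglycerol kinase alpha
4860	Purine nucleoside phosphorylase
5130	Phosphate cytidylyltransferase 1, choline, alpha
5337	Phospholipase D1
5338	Phospholipase D2
9468	Phosphate cytidylyltransferase 1, choline, beta
22978	Ecto-5'-nucleotidase (NTE5), cytosolic II
30814	Phospholipase A2 group IIE
162466	Phosphoethanolamine/phosphocholine phosphatase 1
157	G protein-coupled receptor kinase 3
156	G protein-coupled receptor kinase 2
409	Arrestin beta 2
1103	Choline O-acetyltransferase
7879	RAB7A, member RAS oncogene family
5167	Ectonucleotide pyrophosphatase/phosphodiesterase 1
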