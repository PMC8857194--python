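pathway_name	target_id
Alpha-linolenic acid metabolism	30814
Alpha-linolenic acid metabolism	5319
Amoebiasis	7879
Antifolate resistance	2350
Antifolate resistance	2352
Arachidonic acid metabolism	30814
Arachidonic acid metabolism	5319
Autophagy - animal	7879
Central carbon metabolism in cancer	2263
Chemokine signaling pathway	156
Chemokine signaling pathway	157
Chemokine signaling pathway	409
Choline metabolism in cancer	1606
Choline metabolism in cancer	5130
Choline metabolism in cancer	5337
Choline metabolism in cancer	5338
Choline metabolism in cancer	9468
Cholinergic synapse	1103
Cholinergic synapse	43
Dopaminergic synapse	409
EGFR tyrosine kinase inhibitor resistance	2263
Endocytosis	156
Endocytosis	157
Endocytosis	1601
Endocytosis	2263
Endocytosis	2350
Endocytosis	2352
Endocytosis	409
Endocytosis	5337
Endocytosis	5338
Endocytosis	7879
Ether lipid metabolism	30814
Ether lipid metabolism	5319
Ether lipid metabolism	5337
Ether lipid metabolism	5338
Ether lipid metabolism	79888
Fat digestion and absorption	30814
Fat digestion and absorption	5319
Fc gamma R-mediated phagocytosis	5337
Fc gamma R-mediated phagocytosis	5338
Gastric cancer	2263
Glutamatergic synapse	156
Glutamatergic synapse	157
Glutamatergic synapse	5337
Glutamatergic synapse	5338
Glycerolipid metabolism	1606
Glycerophospholipid metabolism	1103
Glycerophospholipid metabolism	1606
Glycerophospholipid metabolism	162466
Glycerophospholipid metabolism	30814
Glycerophospholipid metabolism	43
Glycerophospholipid metabolism	5130
Glycerophospholipid metabolism	5319
Glycerophospholipid metabolism	5337
Glycerophospholipid metabolism	5338
Glycerophospholipid metabolism	79888
Glycerophospholipid metabolism	9468
GnRH secretion	409
GnRH signaling pathway	5337
GnRH signaling pathway	5338
Hedgehog signaling pathway	156
Hedgehog signaling pathway	157
Hedgehog signaling pathway	409
Linoleic acid metabolism	30814
Linoleic acid metabolism	5319
MAPK signaling pathway	2263
MAPK signaling pathway	409
Metabolic pathways	1606
Metabolic pathways	162466
Metabolic pathways	22978
Metabolic pathways	23475
Metabolic pathways	30814
Metabolic pathways	4837
Metabolic pathways	4860
Metabolic pathways	4907
Metabolic pathways	5130
Metabolic pathways	5167
Metabolic pathways	5319
Metabolic pathways	5337
Metabolic pathways	5338
Metabolic pathways	79888
Metabolic pathways	9468
Mitophagy - animal	7879
Morphine addiction	156
Morphine addiction	157
Morphine addiction	409
Nicotinate and nicotinamide metabolism	22978
Nicotinate and nicotinamide metabolism	23475
Nicotinate and nicotinamide metabolism	4837
Nicotinate and nicotinamide metabolism	4860
Nicotinate and nicotinamide metabolism	4907
Nicotinate and nicotinamide metabolism	5167
Olfactory transduction	156
Olfactory transduction	157
Olfactory transduction	409
PI3K-Akt signaling pathway	2263
Pancreatic cancer	5337
Pancreatic cancer	5338
Pancreatic secretion	30814
Pancreatic secretion	5319
Pantothenate and CoA biosynthesis	5167
Parathyroid hormone synthesis, secretion, and action	409
Parathyroid hormone synthesis, secretion, and action	5337
Parathyroid hormone synthesis, secretion, and action	5338
Pathways in cancer	2263
Pathways in cancer	5337
Pathways in cancer	5338
Phagosome	7879
Phosphatidylinositol signaling system	1606
Phospholipase D signaling pathway	1606
Phospholipase D signaling pathway	5337
Phospholipase D signaling pathway	5338
Phosphonate and phosphinate metabolism	5130
Phosphonate and phosphinate metabolism	9468
Prostate cancer	2263
Purine metabolism	22978
Purine metabolism	4860
Purine metabolism	4907
Purine metabolism	5167
Pyrimidine metabolism	22978
Pyrimidine metabolism	4860
Pyrimidine metabolism	4907
Pyrimidine metabolism	5167
RAS signaling pathway	2263
RAS signaling pathway	30814
RAS signaling pathway	5319
RAS signaling pathway	5337
RAS signaling pathway	5338
Rap1 signaling pathway	2263
Regulation of actin cytoskeleton	2263
Relaxin signaling pathway	409
Riboflavin metabolism	5167
Salmonella infection	7879
Signaling pathways regulating pluripotency of stem cells	2263
Sphingolipid signaling pathway	5337
Sphingolipid signaling pathway	5338
Starch and sucrose metabolism	5167
Tuberculosis	7879
Vascular smooth muscle contraction	30814
Vascular smooth muscle contraction	5319
cAMP signaling pathway	5337
cAMP signaling pathway	5338
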