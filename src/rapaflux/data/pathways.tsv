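pentose_phosphate	Pentose phosphate pathway	glucose 6-phosphate	glucono-1,5-lactone 6-phosphate	6-phospho-gluconate	ribulose 5-phosphate	xylulose 5-phosphate	ribose 5-phosphate	sedoheptulose 7-phosphate	erythrose 4-phosphate
phe_tyr_trp_biosynthesis	Phenylalanine, tyrosine and tryptophan biosynthesis	phosphoenolpyruvate	erythrose 4-phosphate	dahp	shikimate	chorismate	prephenate	anthranilate	indole	tryptophan	phenylalanine	tyrosine
aminoacyl_trna	Aminoacyl-tRNA biosynthesis	alanine	arginine	asparagine	aspartate	cysteine	glutamate	glutamine	glycine	histidine	isoleucine	leucine	lysine	methionine	phenylalanine	proline	serine	threonine	tryptophan	tyrosine	valine
nicotinate_nicotinamide	Nicotinate and nicotinamide metabolism	aspartate	quinolinate	picolinate	nicotinate	nicotinamide	nad	nadp
gly_ser_thr	Glycine, serine and threonine metabolism	glycine	serine	threonine	allothreonine	aspartate	homoserine	glycerate	2-oxobutanoate
val_leu_ile_biosynthesis	Valine, leucine and isoleucine biosynthesis	valine	leucine	isoleucine	threonine	2-oxobutanoate	2-oxoisovalerate
glycolysis	Glycolysis / gluconeogenesis	glucose	glucose 6-phosphate	fructose 6-phosphate	fructose 1,6-bisphosphate	glyceraldehyde 3-phosphate	glycerate 3-phosphate	phosphoenolpyruvate	pyruvate
tca_cycle	Citrate cycle (TCA cycle)	citrate	isocitrate	2-oxoglutarate	succinate	fumarate	malate	oxaloacetate
fatty_acid_biosynthesis	Fatty acid biosynthesis	decanoic acid	dodecanoic acid	tetradecanoic acid	hexadecanoic acid	octadecanoic acid
starch_sucrose	Starch and sucrose metabolism	starch	sucrose	maltose	trehalose	glucose	glucose 1-phosphate
pyruvate_metabolism	Pyruvate metabolism	pyruvate	lactate	acetate	acetyl-coa	oxaloacetate	malate
glyoxylate_dicarboxylate	Glyoxylate and dicarboxylate metabolism	glyoxylate	glycolate	oxalate	malate	citrate	glycerate
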