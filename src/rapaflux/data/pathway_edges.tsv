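pathway	compound_a	compound_b
pentose_phosphate	glucose 6-phosphate	glucono-1,5-lactone 6-phosphate
pentose_phosphate	glucono-1,5-lactone 6-phosphate	6-phospho-gluconate
pentose_phosphate	6-phospho-gluconate	ribulose 5-phosphate
pentose_phosphate	ribulose 5-phosphate	xylulose 5-phosphate
pentose_phosphate	ribulose 5-phosphate	ribose 5-phosphate
pentose_phosphate	ribose 5-phosphate	sedoheptulose 7-phosphate
pentose_phosphate	xylulose 5-phosphate	sedoheptulose 7-phosphate
pentose_phosphate	sedoheptulose 7-phosphate	erythrose 4-phosphate
pentose_phosphate	xylulose 5-phosphate	erythrose 4-phosphate
phe_tyr_trp_biosynthesis	phosphoenolpyruvate	dahp
phe_tyr_trp_biosynthesis	erythrose 4-phosphate	dahp
phe_tyr_trp_biosynthesis	dahp	shikimate
phe_tyr_trp_biosynthesis	shikimate	chorismate
phe_tyr_trp_biosynthesis	chorismate	prephenate
phe_tyr_trp_biosynthesis	prephenate	phenylalanine
phe_tyr_trp_biosynthesis	prephenate	tyrosine
phe_tyr_trp_biosynthesis	chorismate	anthranilate
phe_tyr_trp_biosynthesis	anthranilate	indole
phe_tyr_trp_biosynthesis	indole	tryptophan
nicotinate_nicotinamide	aspartate	quinolinate
nicotinate_nicotinamide	quinolinate	nicotinate
nicotinate_nicotinamide	quinolinate	picolinate
nicotinate_nicotinamide	nicotinate	nad
nicotinate_nicotinamide	nad	nicotinamide
nicotinate_nicotinamide	nad	nadp
nicotinate_nicotinamide	nicotinamide	nicotinate
gly_ser_thr	aspartate	homoserine
gly_ser_thr	homoserine	threonine
gly_ser_thr	threonine	glycine
gly_ser_thr	threonine	allothreonine
gly_ser_thr	threonine	2-oxobutanoate
gly_ser_thr	glycine	serine
gly_ser_thr	serine	glycerate
val_leu_ile_biosynthesis	threonine	2-oxobutanoate
val_leu_ile_biosynthesis	2-oxobutanoate	isoleucine
val_leu_ile_biosynthesis	2-oxoisovalerate	valine
val_leu_ile_biosynthesis	2-oxoisovalerate	leucine
glycolysis	glucose	glucose 6-phosphate
glycolysis	glucose 6-phosphate	fructose 6-phosphate
glycolysis	fructose 6-phosphate	fructose 1,6-bisphosphate
glycolysis	fructose 1,6-bisphosphate	glyceraldehyde 3-phosphate
glycolysis	glyceraldehyde 3-phosphate	glycerate 3-phosphate
glycolysis	glycerate 3-phosphate	phosphoenolpyruvate
glycolysis	phosphoenolpyruvate	pyruvate
tca_cycle	citrate	isocitrate
tca_cycle	isocitrate	2-oxoglutarate
tca_cycle	2-oxoglutarate	succinate
tca_cycle	succinate	fumarate
tca_cycle	fumarate	malate
tca_cycle	malate	oxaloacetate
tca_cycle	oxaloacetate	citrate
fatty_acid_biosynthesis	decanoic acid	dodecanoic acid
fatty_acid_biosynthesis	dodecanoic acid	tetradecanoic acid
fatty_acid_biosynthesis	tetradecanoic acid	hexadecanoic acid
fatty_acid_biosynthesis	hexadecanoic acid	octadecanoic acid
starch_sucrose	starch	maltose
starch_sucrose	maltose	glucose
starch_sucrose	sucrose	glucose
starch_sucrose	glucose	glucose 1-phosphate
starch_sucrose	trehalose	glucose
pyruvate_metabolism	lactate	pyruvate
pyruvate_metabolism	pyruvate	acetyl-coa
pyruvate_metabolism	acetyl-coa	acetate
pyruvate_metabolism	pyruvate	oxaloacetate
pyruvate_metabolism	pyruvate	malate
glyoxylate_dicarboxylate	glyoxylate	glycolate
glyoxylate_dicarboxylate	glyoxylate	oxalate
glyoxylate_dicarboxylate	glyoxylate	malate
glyoxylate_dicarboxylate	malate	citrate
glyoxylate_dicarboxylate	glycerate	glycolate
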