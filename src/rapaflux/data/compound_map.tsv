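metabolite	compound_id
trehalose	trehalose
dodecanoic acid	dodecanoic acid
glucose	glucose
glyoxylic acid	glyoxylate
glycerol	glycerol
fructose 6-phosphate	fructose 6-phosphate
octadecanoic acid	octadecanoic acid
putrescine	putrescine
methylmalonate	methylmalonate
niacinamide	nicotinamide
6-phospho-D-gluconate	6-phospho-gluconate
hexadecanoic acid	hexadecanoic acid
fructose 1,6-bisphosphate	fructose 1,6-bisphosphate
nicotinate	nicotinate
tetradecanoic acid	tetradecanoic acid
glucose 6-phosphate	glucose 6-phosphate
malonic acid	malonate
2-oxobutanoate	2-oxobutanoate
allothreonine	allothreonine
phenylalanine	phenylalanine
tyrosine	tyrosine
aspartic acid	aspartate
threonine	threonine
lactate	lactate
isoleucine	isoleucine
cadaverine	cadaverine
acetoin	acetoin
proline	proline
shikimate	shikimate
lysine	lysine
indole	indole
xylulose 5-phosphate	xylulose 5-phosphate
tryptophan	tryptophan
picolinic acid	picolinate
ribulose 5-phosphate	ribulose 5-phosphate
sedoheptulose 7-phosphate	sedoheptulose 7-phosphate
ethanol	ethanol
erythrose 4-phosphate	erythrose 4-phosphate
ethanedioic acid	oxalate
alanine	alanine
phosphoenolpyruvate	phosphoenolpyruvate
pyruvate	pyruvate
glyceraldehyde 3-phosphate	glyceraldehyde 3-phosphate
glycerate 3-phosphate	glycerate 3-phosphate
succinate	succinate
glycine	glycine
serine	serine
valine	valine
leucine	leucine
methionine	methionine
glutamate	glutamate
glutamine	glutamine
asparagine	asparagine
histidine	histidine
arginine	arginine
citrate	citrate
malate	malate
fumarate	fumarate
2-oxoglutarate	2-oxoglutarate
ribose 5-phosphate	ribose 5-phosphate
glucose 1-phosphate	glucose 1-phosphate
glycerate	glycerate
ornithine	ornithine
decanoic acid	decanoic acid
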