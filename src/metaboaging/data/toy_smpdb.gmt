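valine_leucine_isoleucine_degradation	synthetic SMPDB-style toy pathway	valine	leucine	isoleucine	3_hydroxyisobutyrate	2_oxoisocaproate	isobutyrate	methylmalonate
urea_cycle	synthetic SMPDB-style toy pathway	aspartate	ornithine	arginine	citrulline	urea	fumarate
ammonia_recycling	synthetic SMPDB-style toy pathway	asparagine	aspartate	glutamine	glutamate	glycine	serine
glycolysis	synthetic SMPDB-style toy pathway	glucose	pyruvate	lactate	phosphoenolpyruvate	fructose_1_6_bisphosphate
tryptophan_metabolism	synthetic SMPDB-style toy pathway	tryptophan	kynurenine	serotonin	melatonin
steroid_biosynthesis	synthetic SMPDB-style toy pathway	total_cholesterol	lanosterol	squalene	7_dehydrocholesterol
triacylglycerol_metabolism	synthetic SMPDB-style toy pathway	triacylglyceride	glycerol	palmitate	oleate
ketone_body_metabolism	synthetic SMPDB-style toy pathway	acetone	acetoacetate	3_hydroxybutyrate	acetate
alanine_metabolism	synthetic SMPDB-style toy pathway	alanine	pyruvate	glutamate	2_oxoglutarate
glycine_serine_metabolism	synthetic SMPDB-style toy pathway	glycine	serine	threonine	sarcosine	betaine	dimethylglycine
citric_acid_cycle	synthetic SMPDB-style toy pathway	citrate	succinate	fumarate	malate	oxaloacetate
purine_metabolism	synthetic SMPDB-style toy pathway	uric_acid	hypoxanthine	xanthine	inosine	adenosine
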