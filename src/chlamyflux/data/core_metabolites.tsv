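# Curated core model of C. reinhardtii night-time nitrogen metabolism.
# Energy and redox carriers are internal; their (conserved) carbon moiety is
# excluded from carbon balancing via skip_carbon_check.
metabolite_id	name	carbon_count	skip_carbon_check
G6P	glucose 6-phosphate	6	0
Ac	acetate	2	0
NO3e	extracellular nitrate	0	0
NO2e	extracellular nitrite	0	0
NH4	ammonium	0	0
CO2	carbon dioxide	1	0
Gly	glycine	2	0
Ala	alanine	3	0
Asn	asparagine	4	0
Lys	lysine	6	0
Arg	arginine	6	0
F6P	fructose 6-phosphate	6	0
FBP	fructose 1,6-bisphosphate	6	0
GAP	glyceraldehyde 3-phosphate	3	0
PEP	phosphoenolpyruvate	3	0
Pyr	pyruvate	3	0
AcCoA	acetyl-CoA (acetyl moiety)	2	0
Ru5P	ribulose 5-phosphate	5	0
Cit	citrate	6	0
ICit	isocitrate	6	0
AKG	2-oxoglutarate	5	0
Suc	succinate	4	0
Fum	fumarate	4	0
Mal	malate	4	0
OAA	oxaloacetate	4	0
Glx	glyoxylate	2	0
Glu	glutamate	5	0
Gln	glutamine	5	0
Asp	aspartate	4	0
Ser	serine	3	0
Orn	ornithine	5	0
CP	carbamoyl phosphate	1	0
Citr	citrulline	6	0
ArgSuc	argininosuccinate	10	0
NO3	intracellular nitrate	0	0
NO2	intracellular nitrite	0	0
ATP	ATP	10	1
ADP	ADP	10	1
NAD	NAD+	21	1
NADH	NADH	21	1
NADP	NADP+	21	1
NADPH	NADPH	21	1
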