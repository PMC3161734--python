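# Curated core model of C. reinhardtii night-time nitrogen metabolism.
# Multi-step segments without branch points are lumped into single reactions;
# FAD and ferredoxin are folded onto NAD(H)/NADP(H). Directions follow the
# night-time (heterotrophic, respiratory) physiology; genuinely reversible
# steps keep the <-> token.
reaction_id	equation	enzyme	ec	genes
R_GPI	1 G6P <-> 1 F6P	glucose-6-phosphate isomerase	5.3.1.9	PGI1
R_PFK	1 F6P + 1 ATP -> 1 FBP + 1 ADP	phosphofructokinase	2.7.1.11	PFK1
R_FBA	1 FBP <-> 2 GAP	aldolase + triose-phosphate isomerase (lumped)	4.1.2.13	FBA3
R_GAPDH	1 GAP + 1 NAD + 1 ADP -> 1 PEP + 1 NADH + 1 ATP	lower glycolysis, GAP to PEP (lumped)	1.2.1.12	GAP1
R_PYK	1 PEP + 1 ADP -> 1 Pyr + 1 ATP	pyruvate kinase	2.7.1.40	PYK1
R_PDH	1 Pyr + 1 NAD -> 1 AcCoA + 1 NADH + 1 CO2	pyruvate dehydrogenase complex	1.2.4.1	PDC2
R_G6PDH	1 G6P + 2 NADP -> 1 Ru5P + 2 NADPH + 1 CO2	oxidative pentose phosphate pathway (lumped)	1.1.1.49	GND1
R_TKT	3 Ru5P -> 2 F6P + 1 GAP	non-oxidative pentose phosphate pathway (lumped)	2.2.1.1	TRK1
R_ACS	1 Ac + 2 ATP -> 1 AcCoA + 2 ADP	acetyl-CoA synthetase	6.2.1.1	ACS2
R_CS	1 AcCoA + 1 OAA -> 1 Cit	citrate synthase	2.3.3.1	CIS1
R_ACO	1 Cit <-> 1 ICit	aconitase	4.2.1.3	ACH1
R_IDH	1 ICit + 1 NAD -> 1 AKG + 1 NADH + 1 CO2	isocitrate dehydrogenase (NAD)	1.1.1.41	IDH3
R_IDHP	1 ICit + 1 NADP -> 1 AKG + 1 NADPH + 1 CO2	isocitrate dehydrogenase (NADP)	1.1.1.42	IDH1
R_AKGDH	1 AKG + 1 NAD + 1 ADP -> 1 Suc + 1 NADH + 1 CO2 + 1 ATP	2-oxoglutarate dehydrogenase + succinyl-CoA synthetase (lumped)	1.2.4.2	OGD1
R_SDH	1 Suc + 1 NAD -> 1 Fum + 1 NADH	succinate dehydrogenase	1.3.5.1	SDH1
R_FUM	1 Fum <-> 1 Mal	fumarase	4.2.1.2	FUM1
R_MDH	1 Mal + 1 NAD <-> 1 OAA + 1 NADH	malate dehydrogenase	1.1.1.37	MDH1
R_ICL	1 ICit -> 1 Suc + 1 Glx	isocitrate lyase	4.1.3.1	ICL1
R_MS	1 Glx + 1 AcCoA -> 1 Mal	malate synthase	2.3.3.9	MAS1
R_PEPC	1 PEP + 1 CO2 -> 1 OAA	PEP carboxylase	4.1.1.31	PPC1
R_ME	1 Mal + 1 NADP -> 1 Pyr + 1 CO2 + 1 NADPH	malic enzyme (NADP)	1.1.1.40	MME4
R_NRT	1 NO3e -> 1 NO3	nitrate transporter	-	NRT2.1
R_NIT	1 NO2e -> 1 NO2	nitrite transporter	-	NAR1.1
R_NR	1 NO3 + 1 NADH -> 1 NO2 + 1 NAD	nitrate reductase	1.7.1.1	NIT1
R_NIR	1 NO2 + 3 NADPH -> 1 NH4 + 3 NADP	nitrite reductase	1.7.7.1	NII1
R_GDH	1 AKG + 1 NH4 + 1 NADH -> 1 Glu + 1 NAD	glutamate dehydrogenase	1.4.1.2	GDH1
R_GS	1 Glu + 1 NH4 + 1 ATP -> 1 Gln + 1 ADP	glutamine synthetase	6.3.1.2	GLN1
R_GOGAT	1 Gln + 1 AKG + 1 NADH -> 2 Glu + 1 NAD	glutamate synthase (NADH)	1.4.1.14	GSN1
R_ALAAT	1 Pyr + 1 Glu -> 1 Ala + 1 AKG	alanine aminotransferase	2.6.1.2	AAT1
R_SERS	1 GAP + 1 NAD + 1 Glu -> 1 Ser + 1 NADH + 1 AKG	phosphoserine pathway (lumped)	1.1.1.95	PGDH1
R_SHMT	1 Ser + 1 NADP -> 1 Gly + 1 CO2 + 1 NADPH	serine hydroxymethyltransferase + C1 oxidation (lumped)	2.1.2.1	SHMT1
R_AGT	1 Glx + 1 Glu -> 1 Gly + 1 AKG	glyoxylate aminotransferase	2.6.1.4	AGT1
R_AST	1 OAA + 1 Glu <-> 1 Asp + 1 AKG	aspartate aminotransferase	2.6.1.1	AST1,AST4
R_ASNS	1 Asp + 1 Gln + 1 ATP -> 1 Asn + 1 Glu + 1 ADP	asparagine synthetase	6.3.5.4	ASN1
R_LYSS	1 Asp + 1 Pyr + 1 Glu + 2 NADPH + 1 ATP -> 1 Lys + 1 AKG + 1 CO2 + 2 NADP + 1 ADP	diaminopimelate pathway (lumped)	4.3.3.7	DAP1
R_ORNS	2 Glu + 1 ATP + 1 NADPH -> 1 Orn + 1 AKG + 1 ADP + 1 NADP	ornithine synthesis, N-acetylglutamate route (lumped)	2.6.1.11	ARG1
R_CPS	1 NH4 + 1 CO2 + 2 ATP -> 1 CP + 2 ADP	carbamoyl-phosphate synthetase	6.3.4.16	CMP1
R_OTC	1 Orn + 1 CP -> 1 Citr	ornithine transcarbamylase	2.1.3.3	OTC1
R_ASS	1 Citr + 1 Asp + 1 ATP -> 1 ArgSuc + 1 ADP	argininosuccinate synthetase	6.3.4.5	AGS1
R_ASL	1 ArgSuc -> 1 Arg + 1 Fum	argininosuccinate lyase	4.3.2.1	ARG7
R_ETC	1 NADH + 2 ADP -> 1 NAD + 2 ATP	respiratory chain + ATP synthase (lumped)	-	ETC1
R_ATPM	1 ATP -> 1 ADP	ATP maintenance	-	-
R_NDH	1 NADPH + 1 NAD -> 1 NADP + 1 NADH	NADPH dehydrogenase	1.6.1.1	NDA2
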