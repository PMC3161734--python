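# SYNTHETIC stand-in fixture: 3'-UTR sequences are generated, not genomic.
sequence_id	gene_id	reaction_id	isoform_group
PGI1_3utr	PGI1	R_GPI	gpi
PFK1_3utr	PFK1	R_PFK	pfk
FBA3_3utr	FBA3	R_FBA	fba
GAP1_3utr	GAP1	R_GAPDH	gapdh
PYK1_3utr	PYK1	R_PYK	pyk
PDC2_3utr	PDC2	R_PDH	pdh
GND1_3utr	GND1	R_G6PDH	g6pdh
TRK1_3utr	TRK1	R_TKT	tkt
ACS2_3utr	ACS2	R_ACS	acs
CIS1_3utr	CIS1	R_CS	cs
ACH1_3utr	ACH1	R_ACO	aco
IDH3_3utr	IDH3	R_IDH	idh
IDH1_3utr	IDH1	R_IDHP	idhp
OGD1_3utr	OGD1	R_AKGDH	akgdh
SDH1_3utr	SDH1	R_SDH	sdh
FUM1_3utr	FUM1	R_FUM	fum
MDH1_3utr	MDH1	R_MDH	mdh
ICL1_3utr	ICL1	R_ICL	icl
MAS1_3utr	MAS1	R_MS	ms
PPC1_3utr	PPC1	R_PEPC	pepc
MME4_3utr	MME4	R_ME	me
NRT2.1_3utr	NRT2.1	R_NRT	nrt
NAR1.1_3utr	NAR1.1	R_NIT	nit
NIT1_3utr	NIT1	R_NR	nr
NII1_3utr	NII1	R_NIR	nir
GDH1_3utr	GDH1	R_GDH	gdh
GLN1_3utr	GLN1	R_GS	gs
GSN1_3utr	GSN1	R_GOGAT	gogat
AAT1_3utr	AAT1	R_ALAAT	alaat
PGDH1_3utr	PGDH1	R_SERS	sers
SHMT1_3utr	SHMT1	R_SHMT	shmt
AGT1_3utr	AGT1	R_AGT	agt
AST1_3utr	AST1	R_AST	ast
AST4_3utr	AST4	R_AST	ast
ASN1_3utr	ASN1	R_ASNS	asns
DAP1_3utr	DAP1	R_LYSS	lyss
ARG1_3utr	ARG1	R_ORNS	orns
CMP1_3utr	CMP1	R_CPS	cps
OTC1_3utr	OTC1	R_OTC	otc
AGS1_3utr	AGS1	R_ASS	ass
ARG7_3utr	ARG7	R_ASL	asl
ETC1_3utr	ETC1	R_ETC	etc
NDA2_3utr	NDA2	R_NDH	ndh
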