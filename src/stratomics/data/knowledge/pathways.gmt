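PI3K_AKT_SIGNALING	PI3K-Akt signaling pathway	PIK3CA|1|activator	PIK3R1|1|activator	AKT1|1|activator	AKT2|1|activator	PDPK1|1|activator	MTOR|1|activator	RPS6KB1|1|activator	PTEN|1|inhibitor	TSC1|1|inhibitor	TSC2|1|inhibitor
MAPK_SIGNALING	MAPK signaling pathway	KRAS|1|activator	NRAS|1|activator	HRAS|1|activator	BRAF|1|activator	RAF1|1|activator	MAP2K1|1|activator	MAP2K2|1|activator	MAPK1|1|activator	MAPK3|1|activator	DUSP6|1|inhibitor
HIF1_SIGNALING	HIF-1 signaling pathway	HIF1A|1|activator	ARNT|1|activator	VEGFA|1|activator	SLC2A1|1|activator	LDHA|1|activator	PGK1|1|activator	VHL|1|inhibitor	EGLN1|1|inhibitor
FOCAL_ADHESION	Focal adhesion	PTK2|1|activator	SRC|1|activator	ITGB1|1|activator	ITGA5|1|activator	VCL|1|activator	PXN|1|activator	TLN1|1|activator	FN1|1|activator
CELL_CYCLE	Cell cycle	CCND1|1|activator	CCNE1|1|activator	CDK4|1|activator	CDK6|1|activator	CDK2|1|activator	E2F1|1|activator	MYC|1|activator	RB1|1|inhibitor	CDKN1A|1|inhibitor	CDKN2A|1|inhibitor
P53_SIGNALING	p53 signaling pathway	TP53|1|activator	CDKN1A|1|activator	BAX|1|activator	BBC3|1|activator	GADD45A|1|activator	MDM2|1|inhibitor	MDM4|1|inhibitor
APOPTOSIS	Apoptosis	CASP3|1|activator	CASP8|1|activator	CASP9|1|activator	BAX|1|activator	BAK1|1|activator	APAF1|1|activator	BCL2|1|inhibitor	BCL2L1|1|inhibitor	MCL1|1|inhibitor
ESTROGEN_SIGNALING	Estrogen signaling pathway	ESR1|1|activator	ESR2|1|activator	PGR|1|activator	GREB1|1|activator	TFF1|1|activator	FOXA1|1|activator	GATA3|1|activator	NCOA3|1|activator	APOBEC3B|1|activator
ERBB_SIGNALING	ErbB signaling pathway	ERBB2|1|activator	EGFR|1|activator	ERBB3|1|activator	ERBB4|1|activator	NRG1|1|activator	GRB2|1|activator	SHC1|1|activator	SOS1|1|activator
VEGF_SIGNALING	VEGF signaling pathway	VEGFA|1|activator	VEGFB|1|activator	KDR|1|activator	FLT1|1|activator	FLT4|1|activator	NRP1|1|activator	PTGS2|1|activator
WNT_SIGNALING	Wnt signaling pathway	WNT1|1|activator	WNT3A|1|activator	FZD1|1|activator	LRP6|1|activator	CTNNB1|1|activator	TCF7|1|activator	LEF1|1|activator	APC|1|inhibitor	AXIN1|1|inhibitor	GSK3B|1|inhibitor
NOTCH_SIGNALING	Notch signaling pathway	NOTCH1|1|activator	NOTCH2|1|activator	JAG1|1|activator	JAG2|1|activator	DLL1|1|activator	HES1|1|activator	HEY1|1|activator	NUMB|1|inhibitor
HEDGEHOG_SIGNALING	Hedgehog signaling pathway	SHH|1|activator	SMO|1|activator	GLI1|1|activator	GLI2|1|activator	PTCH1|1|inhibitor	SUFU|1|inhibitor
JAK_STAT_SIGNALING	JAK-STAT signaling pathway	JAK1|1|activator	JAK2|1|activator	STAT1|1|activator	STAT3|1|activator	STAT5A|1|activator	IL6|1|activator	IL6R|1|activator	SOCS1|1|inhibitor	SOCS3|1|inhibitor
MTOR_SIGNALING	mTOR signaling pathway	MTOR|1|activator	RPTOR|1|activator	RICTOR|1|activator	RPS6KB1|1|activator	EIF4EBP1|1|activator	AKT1S1|1|activator	TSC1|1|inhibitor	TSC2|1|inhibitor	STK11|1|inhibitor
TGF_BETA_SIGNALING	TGF-beta signaling pathway	TGFB1|1|activator	TGFBR1|1|activator	TGFBR2|1|activator	SMAD2|1|activator	SMAD3|1|activator	SMAD4|1|activator	SMAD7|1|inhibitor
NFKB_SIGNALING	NF-kappa B signaling pathway	NFKB1|1|activator	RELA|1|activator	IKBKB|1|activator	CHUK|1|activator	TNF|1|activator	IL1B|1|activator	NFKBIA|1|inhibitor
DNA_REPAIR	DNA damage response and repair	BRCA1|1|activator	BRCA2|1|activator	ATM|1|activator	ATR|1|activator	CHEK1|1|activator	CHEK2|1|activator	RAD51|1|activator	PALB2|1|activator	MLH1|1|activator	MSH2|1|activator	PARP1|1|activator
HIPPO_SIGNALING	Hippo signaling pathway	YAP1|1|activator	WWTR1|1|activator	TEAD1|1|activator	LATS1|1|inhibitor	LATS2|1|inhibitor	STK3|1|inhibitor	STK4|1|inhibitor	NF2|1|inhibitor
IMMUNE_CHECKPOINT	Immune checkpoint signaling	CD274|1|activator	PDCD1|1|activator	PDCD1LG2|1|activator	CTLA4|1|activator	LAG3|1|activator	IDO1|1|activator	TIGIT|1|activator	HAVCR2|1|activator
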