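# Miniature gene model fixture (toy genome, 10 chromosomes).
# Columns: gene_id, chrom, start, end (1-based inclusive). The whole
# interval is treated as exonic territory for mutation placement.
gene_id	chrom	start	end
ABCB1	chr1	100001	120000
ABCC1	chr2	100001	120000
ABCG2	chr3	100001	120000
ABL1	chr4	100001	120000
AKT1	chr5	100001	120000
AKT1S1	chr6	100001	120000
AKT2	chr7	100001	120000
ALK	chr8	100001	120000
APAF1	chr9	100001	120000
APC	chr10	100001	120000
APOBEC3B	chr1	1100001	1120000
ARID1A	chr2	1100001	1120000
ARNT	chr3	1100001	1120000
ATM	chr4	1100001	1120000
ATR	chr5	1100001	1120000
AXIN1	chr6	1100001	1120000
BAK1	chr7	1100001	1120000
BAX	chr8	1100001	1120000
BBC3	chr9	1100001	1120000
BCL2	chr10	1100001	1120000
BCL2L1	chr1	2100001	2120000
BRAF	chr2	2100001	2120000
BRCA1	chr3	2100001	2120000
BRCA2	chr4	2100001	2120000
BTK	chr5	2100001	2120000
CASP3	chr6	2100001	2120000
CASP8	chr7	2100001	2120000
CASP9	chr8	2100001	2120000
CCND1	chr9	2100001	2120000
CCNE1	chr10	2100001	2120000
CD274	chr1	3100001	3120000
CDH1	chr2	3100001	3120000
CDK2	chr3	3100001	3120000
CDK4	chr4	3100001	3120000
CDK6	chr5	3100001	3120000
CDKN1A	chr6	3100001	3120000
CDKN2A	chr7	3100001	3120000
CHEK1	chr8	3100001	3120000
CHEK2	chr9	3100001	3120000
CHUK	chr10	3100001	3120000
CTLA4	chr1	4100001	4120000
CTNNB1	chr2	4100001	4120000
CYP19A1	chr3	4100001	4120000
CYP2C19	chr4	4100001	4120000
CYP2C9	chr5	4100001	4120000
CYP2D6	chr6	4100001	4120000
CYP3A4	chr7	4100001	4120000
DLL1	chr8	4100001	4120000
DPYD	chr9	4100001	4120000
DUSP6	chr10	4100001	4120000
E2F1	chr1	5100001	5120000
EGFR	chr2	5100001	5120000
EGLN1	chr3	5100001	5120000
EIF4EBP1	chr4	5100001	5120000
ERBB2	chr5	5100001	5120000
ERBB3	chr6	5100001	5120000
ERBB4	chr7	5100001	5120000
ERCC1	chr8	5100001	5120000
ESR1	chr9	5100001	5120000
ESR2	chr10	5100001	5120000
FANCA	chr1	6100001	6120000
FLT1	chr2	6100001	6120000
FLT4	chr3	6100001	6120000
FN1	chr4	6100001	6120000
FOXA1	chr5	6100001	6120000
FZD1	chr6	6100001	6120000
GADD45A	chr7	6100001	6120000
GATA3	chr8	6100001	6120000
GLI1	chr9	6100001	6120000
GLI2	chr10	6100001	6120000
GRB2	chr1	7100001	7120000
GREB1	chr2	7100001	7120000
GSK3B	chr3	7100001	7120000
HAVCR2	chr4	7100001	7120000
HES1	chr5	7100001	7120000
HEY1	chr6	7100001	7120000
HIF1A	chr7	7100001	7120000
HRAS	chr8	7100001	7120000
IDO1	chr9	7100001	7120000
IKBKB	chr10	7100001	7120000
IL1B	chr1	8100001	8120000
IL6	chr2	8100001	8120000
IL6R	chr3	8100001	8120000
ITGA5	chr4	8100001	8120000
ITGB1	chr5	8100001	8120000
JAG1	chr6	8100001	8120000
JAG2	chr7	8100001	8120000
JAK1	chr8	8100001	8120000
JAK2	chr9	8100001	8120000
KDR	chr10	8100001	8120000
KIT	chr1	9100001	9120000
KRAS	chr2	9100001	9120000
LAG3	chr3	9100001	9120000
LATS1	chr4	9100001	9120000
LATS2	chr5	9100001	9120000
LDHA	chr6	9100001	9120000
LEF1	chr7	9100001	9120000
LRP6	chr8	9100001	9120000
MAP2K1	chr9	9100001	9120000
MAP2K2	chr10	9100001	9120000
MAP3K1	chr1	10100001	10120000
MAPK1	chr2	10100001	10120000
MAPK3	chr3	10100001	10120000
MCL1	chr4	10100001	10120000
MDM2	chr5	10100001	10120000
MDM4	chr6	10100001	10120000
MGMT	chr7	10100001	10120000
MLH1	chr8	10100001	10120000
MSH2	chr9	10100001	10120000
MSH6	chr10	10100001	10120000
MTOR	chr1	11100001	11120000
MYC	chr2	11100001	11120000
NCOA3	chr3	11100001	11120000
NF2	chr4	11100001	11120000
NFKB1	chr5	11100001	11120000
NFKBIA	chr6	11100001	11120000
NOTCH1	chr7	11100001	11120000
NOTCH2	chr8	11100001	11120000
NRAS	chr9	11100001	11120000
NRG1	chr10	11100001	11120000
NRP1	chr1	12100001	12120000
NUMB	chr2	12100001	12120000
PALB2	chr3	12100001	12120000
PARP1	chr4	12100001	12120000
PDCD1	chr5	12100001	12120000
PDCD1LG2	chr6	12100001	12120000
PDGFRA	chr7	12100001	12120000
PDPK1	chr8	12100001	12120000
PGK1	chr9	12100001	12120000
PGR	chr10	12100001	12120000
PIK3CA	chr1	13100001	13120000
PIK3R1	chr2	13100001	13120000
PMS2	chr3	13100001	13120000
PTCH1	chr4	13100001	13120000
PTEN	chr5	13100001	13120000
PTGS2	chr6	13100001	13120000
PTK2	chr7	13100001	13120000
PXN	chr8	13100001	13120000
RAD51	chr9	13100001	13120000
RAF1	chr10	13100001	13120000
RB1	chr1	14100001	14120000
RELA	chr2	14100001	14120000
RICTOR	chr3	14100001	14120000
RPS6KB1	chr4	14100001	14120000
RPTOR	chr5	14100001	14120000
SHC1	chr6	14100001	14120000
SHH	chr7	14100001	14120000
SLC2A1	chr8	14100001	14120000
SMAD2	chr9	14100001	14120000
SMAD3	chr10	14100001	14120000
SMAD4	chr1	15100001	15120000
SMAD7	chr2	15100001	15120000
SMO	chr3	15100001	15120000
SOCS1	chr4	15100001	15120000
SOCS3	chr5	15100001	15120000
SOS1	chr6	15100001	15120000
SRC	chr7	15100001	15120000
STAT1	chr8	15100001	15120000
STAT3	chr9	15100001	15120000
STAT5A	chr10	15100001	15120000
STK11	chr1	16100001	16120000
STK3	chr2	16100001	16120000
STK4	chr3	16100001	16120000
SUFU	chr4	16100001	16120000
TCF7	chr5	16100001	16120000
TEAD1	chr6	16100001	16120000
TFF1	chr7	16100001	16120000
TGFB1	chr8	16100001	16120000
TGFBR1	chr9	16100001	16120000
TGFBR2	chr10	16100001	16120000
TIGIT	chr1	17100001	17120000
TLN1	chr2	17100001	17120000
TNF	chr3	17100001	17120000
TP53	chr4	17100001	17120000
TPMT	chr5	17100001	17120000
TSC1	chr6	17100001	17120000
TSC2	chr7	17100001	17120000
UGT1A1	chr8	17100001	17120000
VCL	chr9	17100001	17120000
VEGFA	chr10	17100001	17120000
VEGFB	chr1	18100001	18120000
VHL	chr2	18100001	18120000
WNT1	chr3	18100001	18120000
WNT3A	chr4	18100001	18120000
WWTR1	chr5	18100001	18120000
XRCC1	chr6	18100001	18120000
YAP1	chr7	18100001	18120000
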