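gene_id	role	priority_weight	source_tag
TP53	tumor_suppressor	1.0	catalog:breast
RB1	tumor_suppressor	0.9	catalog:breast
ATM	tumor_suppressor	0.8	catalog:breast
BRCA1	tumor_suppressor	1.0	catalog:breast
BRCA2	tumor_suppressor	1.0	catalog:breast
PTEN	tumor_suppressor	0.9	catalog:breast
PIK3CA	oncogene	1.0	catalog:breast
ERBB2	oncogene	1.0	catalog:breast
ESR1	oncogene	0.9	catalog:breast
KRAS	oncogene	0.8	catalog:pan-cancer
NRAS	oncogene	0.7	catalog:pan-cancer
HRAS	oncogene	0.6	catalog:pan-cancer
BRAF	oncogene	0.8	catalog:pan-cancer
EGFR	oncogene	0.8	catalog:pan-cancer
MYC	oncogene	0.8	catalog:breast
CCND1	oncogene	0.8	catalog:breast
CDH1	tumor_suppressor	0.9	catalog:breast
GATA3	tumor_suppressor	0.9	catalog:breast
MAP3K1	tumor_suppressor	0.7	catalog:breast
AKT1	oncogene	0.8	catalog:breast
CDKN2A	tumor_suppressor	0.7	catalog:pan-cancer
FOXA1	oncogene	0.7	catalog:breast
NOTCH1	ambiguous	0.6	catalog:pan-cancer
ARID1A	tumor_suppressor	0.7	catalog:pan-cancer
APC	tumor_suppressor	0.6	catalog:pan-cancer
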