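# Curated gene list resources used by the immunotherapy and pharmacogenomics
# assessments. Fixture curation; replace with an institutional list as needed.
version: "2026.1"
lists:
  dna_repair: [BRCA1, BRCA2, ATM, ATR, CHEK1, CHEK2, MLH1, MSH2, MSH6, PMS2, PALB2, RAD51, FANCA, XRCC1, ERCC1, MGMT]
  checkpoint_biomarkers: [CD274, PDCD1, PDCD1LG2, CTLA4, LAG3, HAVCR2, TIGIT, IDO1]
  efflux_transporters: [ABCB1, ABCC1, ABCG2]
  drug_metabolizing_enzymes: [CYP2D6, CYP3A4, CYP2C9, CYP2C19, CYP19A1, DPYD, UGT1A1, TPMT]
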