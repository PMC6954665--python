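# stratomics

Headless decision-support analytics for breast cancer treatment
stratification. Given one tumor sample — clinical markers (ER/PR/HER2,
menopausal status, grade, TNM, Ki-67), gene expression with matched
controls, somatic/germline mutations (VCF), copy-number segments (SEG) and
promoter methylation — the package computes an integrated molecular
portrait and evaluates therapy options against a declarative knowledge
base, emitting an auditable JSON report and visualization-ready data
exports (no images, no web front-end).

It is written for bioinformaticians building molecular tumor-board
tooling: every verdict decomposes into itemized, referenced evidence, every
stochastic stage is seeded, and every input is reproducible from the
bundled synthetic generator, so the full pipeline is testable offline.

## What it computes

* **Deregulation scores** — per gene, log2 fold-change against one control
  (`log2((t+c₀)/(c+c₀))`, pseudocount c₀=1) or a z-score against ≥2
  controls (`(t − mean(c)) / sd(c)`, sample sd).
* **Pathway activities** — for 20 core cancer pathways, the raw score is
  the weighted sum `S = Σ_g w_g · z_g` over member genes (inhibitors enter
  negatively). Activity is the midrank position of `S` within a permutation
  null (gene→score assignment permuted over all scored genes, default
  n_perm = 1000), so it lives on [0, 1] with 0.5 = "indistinguishable from
  random gene sets". Two-sided empirical P with add-one correction,
  `p = (1 + #{|S_perm| ≥ |S|}) / (n_perm + 1)`, Benjamini–Hochberg
  adjusted across pathways. Labels: *medium* on [0.4, 0.6], *high* on
  (0.6, 1], *low* below. Reference samples rank by mean-squared distance of
  activity vectors.
* **Driver events** — catalog genes with ≥1 altered channel (graded
  mutation, non-neutral CNA call at |log2 ratio| ≥ 0.3, strong methylation
  or expression change), prioritized by
  `weight × severity_points + extra_channels` with severity graded from
  impact/SIFT/PolyPhen (severe ≻ damaging ≻ moderate ≻ low).
* **Intrinsic subtype** — k-NN call (k=15) against a labeled reference
  cohort in cohort-standardized expression space, plus PCA/t-SNE
  embeddings for plotting.
* **Drug assessment** — 17 standard-of-care and 23 off-label
  driver-targeting drugs, each a list of rule items over biomarkers,
  targets, metabolizing enzymes, efflux transporters, pathways and genomic
  markers. Fired biomarker/enzyme contraindications are decisive
  gatekeepers; clinical-vs-omics consistency checks flag e.g. a
  HER2-negative sample with ERBB2 overexpression.
* **Immunotherapy markers** — tumor mutational burden (somatic mutations
  per megabase exon) with cohort midrank percentile, DNA-repair gene
  impairment, checkpoint-biomarker overview.

## Worked example

`examples/03_drug_assessment.py` generates the tamoxifen-resistance case
(hormone-receptor-positive, HER2-negative, premenopausal; germline CYP2D6
frameshift; somatic ESR2 frameshift; APOBEC3B up; BRCA1/2 germline loss
with PARP1 z = 4.99) and runs the full pipeline:

```
drug                                  verdict   +   -
tamoxifen                     contraindicated   3   4
anastrozole                       conditional   2   1
...
olaparib                            suggested   3   0

tamoxifen evidence against:
  [target] ESR2 mutation grade severe exceeds allowed moderate (possible resistance mutation) (PMID:9643506 ...)
  [metabolizing_enzyme] CYP2D6 loss-of-function: likely poor metabolizer phenotype (grade severe) (PMID:16361630 ...)
  [genomic_marker] APOBEC3B deregulation 2.80 vs threshold 2 (PMID:26649648 ...)
  [pathway] pathway MAPK_SIGNALING activity label high (PMID:21779440 ...)

consistency warnings: ['clinical her2_status negative but ERBB2 strongly overexpressed (score 2.50)']
```

Tamoxifen is contraindicated despite favorable receptor status: the sample
cannot activate the prodrug (CYP2D6 loss), its target carries a severe
mutation, and resistance-associated APOBEC3B/MAPK signals are present —
while the PARP inhibitor is suggested on BRCA1/2 loss with PARP1
upregulation. `examples/04_tmb_immunotherapy.py` prints, for the
triple-negative case, `TMB: 13.37 mutations/Mb (cohort percentile 99.6)`
with TP53/RB1/ATM at the top of the driver list — the constellation in
which checkpoint blockade is considered.

Other entry points: `examples/01_pathway_activities.py` (permutation-based
pathway scoring), `examples/02_subtype_call.py` (k-NN subtype call),
`examples/05_full_report.py` (all JSON/TSV exports), and the `stratomics`
CLI (`generate`, `run`, `pathways`, `tmb`, `drugs`, `subtype`).

## Scope

The package consumes effect-predictor annotations (VCF CSQ/ANN or side
tables) but does not run VeP; it ships a curated fixture knowledge bundle
(correct cardinalities, literature-named members, synthetic identifier
cross-references) rather than redistributing licensed database content; and
neoepitope prediction, HLA typing and clinical-trial matching are out of
scope. See `docs/methods.md` for the model details and design decisions.
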