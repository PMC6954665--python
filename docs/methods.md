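# Methods

This note documents the models, parameters, numerical choices and known
limitations of stratomics. It is the package's own account of its science;
empirical claims below are the ones the test suite and
`scripts/acceptance.py` themselves compute.

## Input harmonization

All omics channels are re-keyed to a single namespace (HGNC symbols) before
integration. The input namespace is auto-detected by a regex majority vote
(Ensembl `ENSG…`, numeric Entrez, UniProt accession pattern, otherwise
symbol); a minority share above 20% is fatal ("ambiguous namespace") since
a silently mixed table usually indicates an upstream join error.
Identifiers missing from the cross-reference are kept under a reserved
`unmapped:` prefix, which makes the mapping total and idempotent — both
properties are tested. Many-to-one collisions resolve to the
lexicographically smallest symbol with a warning. The bundled
cross-reference carries real accessions for a handful of well-known genes
and deterministic synthetic accessions for the rest (marked per row); it is
a fixture standing in for a full HGNC/Ensembl/UniProt dump and is
replaceable file-for-file.

Coordinates: VCF and SEG enter in their native 1-based conventions and are
converted exactly once, at the parser boundary, to 0-based half-open
intervals (`segments.py` documents this); all downstream interval
arithmetic assumes that convention. Overlapping SEG segments are resolved
at read time into disjoint pieces carrying the per-base mean of their
covering segments, with a warning.

## Deregulation scores

One control: `log2((t + c0) / (c + c0))` with pseudocount `c0 = 1`
(configurable), the standard stabilizer for count-like expression values.
Two or more controls: z-score with the sample (n−1) standard deviation;
genes with zero control spread get score 0 and a flag rather than ±∞.
Methylation uses the same machinery on beta values with `c0 = 0.01`, a
pseudocount scaled to the [0, 1] beta range. Duplicate gene rows collapse
to their mean (deterministic and order-independent). The comparator
(matched normal vs. other tumors) is recorded in provenance but not
treated differently — the score semantics are identical either way, only
the interpretation shifts.

## Pathway activity

The raw pathway score is `S = Σ_g w_g · z_g` over scored members, with
inhibitor members entering negatively. Default weights are ±1; the scoring
is weight-agnostic, so a curation with calibrated weights drops in
unchanged.

The mapping of `S` to the [0, 1] activity scale is the package's own
choice: the midrank position of `S` inside its permutation null,
`(#{null < S} + (#{null = S} + 1)/2) / (n_perm + 1)`. This is rank-based
and scale-free — doubling every deregulation score leaves activity and P
unchanged when the null is recomputed (tested) — and yields exactly 0.5
for all-zero deregulation by the tie midrank. The null permutes the
gene→score assignment over *all* scored genes (not only pathway-annotated
ones), recomputing `S` per draw; within one sample the permutations are
shared across pathways for speed, which leaves each pathway's marginal
null distribution unchanged.

Significance: two-sided add-one empirical P,
`p = (1 + #{|S_perm| ≥ |S|}) / (n_perm + 1)`, so a pathway can be
significantly *inactive* as well as active; `n_perm` defaults to 1000
(user-configurable, minimum 100), seed defaults to 42. An exhaustive
enumeration mode exists for tiny universes and is checked against an
independent brute-force oracle. BH adjustment is delegated to statsmodels
(`fdr_bh`) behind the `adjust_bh` surface and verified elementwise against
a textbook step-up implementation in the tests. Pathways with fewer than
25% of members scored are "not assessable" and excluded from labels,
radar export and similarity.

Labels: *medium* on the closed interval [0.4, 0.6], *high* on (0.6, 1],
*low* on the complement. Reference-sample similarity is the mean-squared
distance of activity vectors with unassessable pathways dropped pairwise,
ties broken by sample id.

## Subtype call

The published presentation of intrinsic subtype is visual (PCA/t-SNE
scatter); to make it testable the package adds an explicit k-NN caller:
majority label among the k = 15 nearest cohort samples by Euclidean
distance in cohort-standardized space, ties toward the smaller mean
distance. Genes are standardized by *cohort* mean/sd so the query cannot
shift the reference frame; zero-variance genes are dropped, and by default
the top 2000 cohort-variance genes are used (the full panel when smaller).
PCA fixes component signs by the largest-|loading| convention so
embeddings are reproducible; t-SNE is seeded with perplexity
min(30, (n−1)/3). A query covering less than half the cohort panel is
rejected.

## Driver events and severity

Severity grading follows the upstream predictors' published conventions:
impact HIGH → *severe*; MODERATE with SIFT < 0.05 or PolyPhen > 0.85 →
*damaging*; other MODERATE → *moderate*; LOW → *low*; else *unknown*.
CNA calls use ±0.3 log2-ratio thresholds (common practice for segmented
ratios; configurable), with per-gene values as the length-weighted mean of
overlapping segments — verified against a per-base accumulation oracle.
A catalog gene becomes a driver event with ≥1 altered channel; the
priority score `weight × severity_points + (channels − 1)` (severe 3,
damaging 2, moderate 1) is an explicit surrogate for a prioritization the
published tool presents but does not formalize. Gating on catalog
membership mirrors a curated-lookup design; the package does no de novo
driver discovery.

## Drug rules and verdicts

Rule items are declarative, with a closed predicate vocabulary
(status_equals, expression_above/below, lof_mutation_present,
any_mutation_present, severity_at_most, activity_label_in,
copy_number_above, mutation_absent). "Highly expressed" defaults to
z ≥ 2 or log2 fold-change ≥ 1, overridable per item. Evaluation is a pure
function of (knowledge, bundle, activities); unresolvable subjects yield
unfired "not assessable" items rather than errors.

Verdict aggregation is likewise an explicit surrogate — the source
presentation lists per-factor indicators without combining them:
*contraindicated* on any fired decisive biomarker/enzyme contraindication
(receptor status and prodrug activation act as gatekeepers) or ≥2 fired
contraindications of any kind; *suggested* on support without
contraindication; *conditional* in between; *not assessable* when nothing
could be evaluated. Menopausal-status items for aromatase inhibitors carry
`decisive: false` so a premenopausal patient demotes them to *conditional*
(ovary-suppression note in the explanation) instead of hard
contraindication. A lone non-decisive contraindication without support
also yields *conditional* — the evidence is against, but not decisively.

The bundle cardinalities (20 pathways, 17 SOC drugs, 23 driver-targeting
drugs) are enforced at load time, and the full drug-rule table mixes
literature-named entries with schema-faithful placeholders, each tagged
`curation:` accordingly.

## Tumor mutational burden

TMB = unique somatic variants (per chrom/pos/ref/alt — duplicates from
multi-caller inputs count once) per megabase of exonic territory. When
exon intervals are supplied only variants inside them count; otherwise all
somatic variants count, and the report flags which mode was used.
`exome_mb` is an explicit parameter (default 30 Mb for real exomes; the
pipeline defaults to the toy genome's 3.74 Mb territory stated in the
fixture manifest). The cohort percentile is the midrank position within
the cohort TMB vector times 100; with a strictly positive cohort a TMB of
exactly 0 therefore lands at `50/(n+1)` percent rather than exactly 0 —
the midrank convention is kept for consistency with the activity scale.
Repair genes are *impaired* iff their best mutation grade is severe or
damaging. Neoepitope prediction and HLA typing are external steps; the
report carries a note, not results.

## Synthetic data

The generator defines the study conditions. The shared panel is all 187
knowledge-base genes plus synthetic fillers to 1500 genes on a toy
10-chromosome genome (gene models 20 kb, non-overlapping). Expression is
Gaussian on the log2 scale around baseline 8 with noise sd 1. Controls are
the deterministic triple (mu − sd, mu, mu + sd), whose sample mean and sd
are exactly (mu, sd) — so planted tumor values `mu + z·sd` reproduce their
target z-scores *exactly* through the real deregulation computation (the
case fixtures plant z = 3.63 for VEGFA and z = 4.99 for PARP1, the values
reported for the corresponding public tumor samples).

The reference cohort (default 30 samples per subtype, seed 7) combines
curated marker blocks (ER/PR program for luminal, ERBB2 block for
HER2-enriched, proliferation block separating luminal A/B, focal-adhesion/
HIF/MAPK block for basal-like) with a broad per-subtype transcriptional
program over a fixed quarter of the filler genes (shift +1.5). The broad
programs reflect that real intrinsic subtypes differ genome-wide, not only
at receptor loci, and are a deterministic function of the panel — cohorts
at different seeds share centroids, which is what makes held-out recovery
meaningful. Cohort pathway activities are computed through the real
scoring pipeline (n_perm 200); cohort TMB values are lognormal(0, 0.8),
median ≈ 1 mutation/Mb with a high tail. Case tumors additionally carry
their subtype's broad program on the fillers.

What the generator does **not** emulate: mutational signatures, linkage
and copy-number co-segregation, platform effects, tumor purity gradients,
or realistic gene-gene correlation. Passing tests therefore demonstrate
that the algorithms recover *planted* structure under Gaussian noise, not
performance on real tumors.

## Problem sizes and determinism

Default analysis sizes: 1500-gene panel, 120-sample cohort, n_perm 1000
for single-sample pathway scoring (tests and the acceptance script use
200–500), 200 null pathways for calibration, 40 held-out samples for
recovery. Every stochastic stage takes an explicit seed; reports contain
no timestamps, so identical configurations produce byte-identical output,
and the knowledge bundle's SHA-256 content hash is recorded for
provenance.

## Known limitations

* The [0, 1] activity normalization is a rank-based surrogate; it
  reproduces the scale and labels of the original presentation but not
  necessarily its exact activity numbers, whose derivation is not public.
* Verdict aggregation and the driver priority score are explicit,
  documented surrogates (see above).
* CYP2D6 loss is inferred from consequence class only — no star-allele
  diplotype calling.
* Gene-level methylation only; no probe-level analysis, no liftover, no
  FASTQ/BAM processing.
* The knowledge bundle is a curated fixture: cardinalities and named
  members are faithful, placeholder entries are marked, and the schemas
  accept a full curation as a drop-in replacement.
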