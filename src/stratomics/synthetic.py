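"""Self-contained synthetic inputs: tumor case bundles and a labeled
reference cohort with planted, verifiable structure.

Expression is Gaussian on the log2 scale around a common baseline. Control
profiles are generated as the deterministic triple (mu - sd, mu, mu + sd) per
gene, whose sample mean is exactly mu and sample standard deviation exactly
sd — so a tumor value mu + z*sd yields *exactly* the planted z-score through
the real deregulation computation. Case templates mirror three archetypal
tumors:

* ``case1_pathway`` — ER-/PR+/HER2- tumor with strongly active MAPK, HIF-1
  and focal-adhesion programs, inactive PI3K-Akt, and VEGFA upregulation.
* ``case2_tamoxifen`` — hormone-receptor-positive, HER2-negative,
  premenopausal tumor carrying a germline CYP2D6 frameshift (poor
  metabolizer), a somatic ESR2 frameshift, APOBEC3B and ERBB2 upregulation,
  germline BRCA1/2 loss with strong PARP1 upregulation.
* ``case3_immuno`` — triple-negative metastatic tumor with 50 somatic exonic
  mutations (high mutational burden for the toy exome), severe/damaging
  TP53, RB1 and ATM mutations and additional repair-gene hits.

Every plant is listed in a manifest JSON so tests can assert it end to end.
The toy genome has 10 chromosomes; its exonic territory (sum of the gene
model intervals) is stated in the manifest and used as the TMB denominator.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .clinical import ClinicalRecord, write_clinical
from .errors import InputError
from .expression import ExpressionTable, compute_deregulation, write_expression
from .knowledge import KnowledgeBundle, load_knowledge_base
from .methylation import MethylationTable, write_methylation
from .pathways import score_pathways, activity_vector
from .segments import SegmentRecord, write_seg
from .subtyping import ReferenceCohort, SUBTYPES
from .variants import MutationRecord, write_vcf

CONTIGS = [f"chr{i}" for i in range(1, 11)]
BASELINE = 8.0
CASE_TEMPLATES = ("case1_pathway", "case2_tamoxifen", "case3_immuno", "random")

ER_BLOCK = ["ESR1", "ESR2", "PGR", "FOXA1", "GATA3", "TFF1", "GREB1", "NCOA3"]
HER2_BLOCK = ["ERBB2", "ERBB3", "GRB2"]
PROLIF_BLOCK = ["CCNE1", "CDK4", "CDK6", "CDK2", "E2F1", "MYC", "CCND1"]
BASAL_BLOCK = ["PTK2", "SRC", "ITGB1", "ITGA5", "VCL", "PXN", "TLN1", "FN1",
               "HIF1A", "VEGFA", "SLC2A1", "LDHA", "PGK1", "KRAS", "NRAS", "BRAF"]

SUBTYPE_SHIFTS = {
    "luminal A": {**{g: 3.0 for g in ER_BLOCK}, **{g: -1.0 for g in PROLIF_BLOCK}},
    "luminal B": {**{g: 2.5 for g in ER_BLOCK}, **{g: 2.0 for g in PROLIF_BLOCK}},
    "HER2-enriched": {**{g: 4.0 for g in HER2_BLOCK}, **{g: -1.0 for g in ER_BLOCK},
                      **{g: 1.0 for g in PROLIF_BLOCK}},
    "basal-like": {**{g: 2.5 for g in BASAL_BLOCK}, **{g: -2.5 for g in ER_BLOCK},
                   **{g: -1.0 for g in HER2_BLOCK}},
}


@dataclass
class CohortSpec:
    n_per_subtype: int = 30
    n_genes: int = 1500
    noise_sd: float = 1.0
    seed: int = 7
    activity_n_perm: int = 200


@dataclass
class CaseSpec:
    template: str = "random"
    seed: int = 0

    def __post_init__(self):
        if self.template not in CASE_TEMPLATES:
            raise InputError(f"unknown case template {self.template!r}; "
                             f"choose from {CASE_TEMPLATES}")


def gene_panel(n_genes: int = 1500, kb: Optional[KnowledgeBundle] = None) -> List[str]:
    """Shared panel: all knowledge-base genes plus synthetic filler genes."""
    kb = kb or load_knowledge_base()
    known = sorted({m.gene_id for m in kb.gene_models})
    if n_genes < len(known):
        raise InputError(f"n_genes must be >= {len(known)} (knowledge genes)")
    fillers = [f"SYN{i:04d}" for i in range(1, n_genes - len(known) + 1)]
    return known + fillers


def exome_megabases(kb: Optional[KnowledgeBundle] = None) -> float:
    kb = kb or load_knowledge_base()
    return sum(m.end - m.start for m in kb.gene_models) / 1e6


def _control_matrix(mu: np.ndarray, sd: float = 1.0) -> np.ndarray:
    """Three controls per gene with sample mean exactly mu, sample sd exactly sd."""
    return np.stack([mu - sd, mu, mu + sd], axis=1)


PROGRAM_SHIFT = 1.5


def _subtype_centroid(subtype: str, panel: Sequence[str]) -> np.ndarray:
    """Centroid shift vector: curated marker blocks plus a broad subtype
    transcriptional program over a fixed quarter of the filler genes.

    Real intrinsic subtypes differ genome-wide, not only at receptor loci;
    the filler programs carry that broad signal. They are a deterministic
    function of the panel (not the seed), so cohorts generated with
    different seeds share the same centroids.
    """
    idx = {g: i for i, g in enumerate(panel)}
    shift = np.zeros(len(panel))
    for g, s in SUBTYPE_SHIFTS[subtype].items():
        shift[idx[g]] = s
    fillers = [i for i, g in enumerate(panel) if g.startswith("SYN")]
    k = list(SUBTYPE_SHIFTS).index(subtype)
    block = len(fillers) // 4
    for i in fillers[k * block:(k + 1) * block]:
        shift[i] = PROGRAM_SHIFT
    return shift


def generate_cohort(spec: CohortSpec = CohortSpec(),
                    kb: Optional[KnowledgeBundle] = None) -> ReferenceCohort:
    """Labeled 4-subtype reference cohort with expression, the pathway
    activity matrix computed through the real scoring pipeline, and a cohort
    TMB vector."""
    kb = kb or load_knowledge_base()
    rng = np.random.default_rng(spec.seed)
    panel = gene_panel(spec.n_genes, kb)
    mu = np.full(len(panel), BASELINE)

    sample_ids, labels, rows = [], {}, []
    for subtype in SUBTYPES:
        shift = _subtype_centroid(subtype, panel)
        for j in range(spec.n_per_subtype):
            sid = f"{subtype.replace(' ', '_')}_{j:03d}"
            rows.append(mu + shift + rng.normal(0, spec.noise_sd, len(panel)))
            sample_ids.append(sid)
            labels[sid] = subtype
    expression = np.array(rows)

    controls = _control_matrix(mu)
    pathway_ids = [p.pathway_id for p in kb.pathways]
    activities = {}
    for sid, x in zip(sample_ids, expression):
        dereg = compute_deregulation(ExpressionTable(panel, x, controls))
        results = score_pathways(dereg, kb, n_perm=spec.activity_n_perm, seed=spec.seed)
        activities[sid] = activity_vector(sid, results).activities
    activity_matrix = pd.DataFrame.from_dict(activities, orient="index",
                                             columns=pathway_ids).loc[sample_ids]

    # mutation loads per Mb: roughly lognormal, median near 1/Mb with a high tail
    tmb_values = dict(zip(sample_ids,
                          rng.lognormal(mean=0.0, sigma=0.8, size=len(sample_ids))))
    return ReferenceCohort(genes=panel, expression=expression, sample_ids=sample_ids,
                           labels=labels, activity_matrix=activity_matrix,
                           tmb_values=tmb_values)


def _variant(kb: KnowledgeBundle, gene: str, origin: str, consequence: str,
             impact: str, offset: int = 500, sift: float = None,
             polyphen: float = None, ref: str = "A", alt: str = "T") -> MutationRecord:
    model = kb.model_for(gene)
    if model is None:
        raise InputError(f"synthetic variant: no gene model for {gene}")
    return MutationRecord(chrom=model.chrom, pos=model.start + 1 + offset, ref=ref,
                          alt=alt, origin=origin, gene_id=gene, consequence=consequence,
                          impact=impact, sift=sift, polyphen=polyphen)


def _case_clinical(template: str) -> ClinicalRecord:
    if template == "case1_pathway":
        return ClinicalRecord("CASE1", er_status="negative", pr_status="positive",
                              her2_status="negative", menopausal_status="post",
                              grade=3, tnm=("T3", "N1", "M0"), ki67_percent=40.0,
                              sample_origin="primary", tumor_cell_fraction=0.7)
    if template == "case2_tamoxifen":
        return ClinicalRecord("CASE2", er_status="positive", pr_status="positive",
                              her2_status="negative", menopausal_status="pre",
                              grade=2, tnm=("T2", "N0", "M0"), ki67_percent=25.0,
                              sample_origin="primary", tumor_cell_fraction=0.6)
    if template == "case3_immuno":
        return ClinicalRecord("CASE3", er_status="negative", pr_status="negative",
                              her2_status="negative", menopausal_status="post",
                              grade=3, tnm=("T4", "N2", "M1"), ki67_percent=60.0,
                              sample_origin="metastasis", tumor_cell_fraction=0.8)
    return ClinicalRecord("RANDOM", er_status="positive", pr_status="negative",
                          her2_status="negative", menopausal_status="post", grade=2,
                          sample_origin="primary")


def _case_expression_plants(template: str) -> Dict[str, float]:
    """Planted exact z-scores per template (everything else is noise)."""
    if template == "case1_pathway":
        plants = {g: 3.0 for g in ("BRAF", "KRAS", "NRAS", "MAP2K1", "MAPK1", "MAPK3")}
        plants["VEGFA"] = 3.63
        plants.update({g: 2.5 for g in ("HIF1A", "SLC2A1", "LDHA", "PGK1",
                                        "PTK2", "ITGB1", "FN1", "SRC")})
        plants.update({g: -2.5 for g in ("PIK3CA", "PIK3R1", "AKT1", "AKT2",
                                         "MTOR", "RPS6KB1")})
        return plants
    if template == "case2_tamoxifen":
        plants = {"ESR1": 2.5, "PGR": 2.5, "FOXA1": 2.0, "GATA3": 2.0, "TFF1": 2.0,
                  "GREB1": 2.0, "APOBEC3B": 2.8, "ERBB2": 2.5, "PARP1": 4.99}
        plants.update({g: 2.8 for g in ("BRAF", "KRAS", "NRAS", "MAP2K1",
                                        "MAPK1", "MAPK3")})
        return plants
    if template == "case3_immuno":
        plants = {g: -2.5 for g in ER_BLOCK}
        plants.update({g: 2.5 for g in ("PTK2", "ITGB1", "FN1", "HIF1A",
                                        "SLC2A1", "CD274", "PDCD1LG2")})
        return plants
    return {}


def _case_variants(template: str, kb: KnowledgeBundle, rng: np.random.Generator
                   ) -> Tuple[List[MutationRecord], List[MutationRecord]]:
    somatic: List[MutationRecord] = []
    germline: List[MutationRecord] = []
    if template == "case1_pathway":
        somatic.append(_variant(kb, "BRAF", "somatic", "missense_variant", "MODERATE",
                                sift=0.3, polyphen=0.4))
        somatic.append(_variant(kb, "KRAS", "somatic", "missense_variant", "MODERATE",
                                sift=0.2, polyphen=0.5))
    elif template == "case2_tamoxifen":
        germline.append(_variant(kb, "CYP2D6", "germline", "frameshift_variant", "HIGH",
                                 ref="AT", alt="A"))
        germline.append(_variant(kb, "BRCA1", "germline", "frameshift_variant", "HIGH",
                                 ref="CA", alt="C"))
        germline.append(_variant(kb, "BRCA2", "germline", "stop_gained", "HIGH",
                                 ref="C", alt="T"))
        somatic.append(_variant(kb, "ESR2", "somatic", "frameshift_variant", "HIGH",
                                ref="GT", alt="G"))
        somatic.append(_variant(kb, "ERBB2", "somatic", "missense_variant", "MODERATE",
                                sift=0.3, polyphen=0.5))
    elif template == "case3_immuno":
        somatic.append(_variant(kb, "TP53", "somatic", "stop_gained", "HIGH",
                                ref="C", alt="T"))
        somatic.append(_variant(kb, "RB1", "somatic", "frameshift_variant", "HIGH",
                                ref="TG", alt="T"))
        somatic.append(_variant(kb, "ATM", "somatic", "missense_variant", "MODERATE",
                                sift=0.01, polyphen=0.95))
        somatic.append(_variant(kb, "MLH1", "somatic", "missense_variant", "MODERATE",
                                sift=0.02, polyphen=0.9))
        somatic.append(_variant(kb, "MSH2", "somatic", "frameshift_variant", "HIGH",
                                ref="AC", alt="A"))
        # passengers: fill up to exactly 50 unique somatic exonic variants
        models = [m for m in kb.gene_models
                  if m.gene_id not in {"TP53", "RB1", "ATM", "MLH1", "MSH2"}]
        picks = rng.choice(len(models), size=45, replace=False)
        for i, pi in enumerate(picks):
            m = models[pi]
            cons = "missense_variant" if i % 2 == 0 else "synonymous_variant"
            impact = "MODERATE" if cons == "missense_variant" else "LOW"
            somatic.append(MutationRecord(
                chrom=m.chrom, pos=m.start + 1 + int(rng.integers(0, m.end - m.start)),
                ref="G", alt="C", origin="somatic", gene_id=m.gene_id,
                consequence=cons, impact=impact,
                sift=0.6 if cons == "missense_variant" else None,
                polyphen=0.2 if cons == "missense_variant" else None))
    else:  # random
        models = kb.gene_models
        picks = rng.choice(len(models), size=8, replace=False)
        for pi in picks:
            m = models[pi]
            somatic.append(MutationRecord(
                chrom=m.chrom, pos=m.start + 1 + int(rng.integers(0, m.end - m.start)),
                ref="A", alt="G", origin="somatic", gene_id=m.gene_id,
                consequence="missense_variant", impact="MODERATE",
                sift=float(np.round(rng.uniform(0, 1), 2)), polyphen=None))
    return somatic, germline


def _case_segments(template: str, rng: np.random.Generator,
                   kb: KnowledgeBundle) -> List[SegmentRecord]:
    segments: List[SegmentRecord] = []
    for chrom in CONTIGS:
        cut = int(rng.integers(5_000_000, 15_000_000))
        for a, b in ((0, cut), (cut, 25_000_000)):
            segments.append(SegmentRecord(chrom, a, b,
                                          float(np.round(rng.normal(0, 0.05), 3))))
    if template == "case2_tamoxifen":
        # focal CCND1 amplification on top of the neutral background
        m = kb.model_for("CCND1")
        segments.append(SegmentRecord(m.chrom, m.start - 50_000, m.end + 50_000, 0.9))
    return segments


def _case_methylation(panel: Sequence[str], template: str,
                      rng: np.random.Generator) -> MethylationTable:
    n = len(panel)
    mu = np.clip(rng.uniform(0.2, 0.6, n), 0.02, 0.93)
    sd = 0.02
    controls = np.stack([mu - sd, mu, mu + sd], axis=1)
    tumor = np.clip(mu + rng.normal(0, sd, n), 0.0, 1.0)
    if template == "case3_immuno":
        i = list(panel).index("MGMT")
        tumor[i] = min(1.0, mu[i] + 10 * sd)  # promoter hypermethylation plant
    return MethylationTable(list(panel), tumor, controls)


def generate_case(spec: CaseSpec, outdir, n_genes: int = 1500,
                  kb: Optional[KnowledgeBundle] = None) -> dict:
    """Write the full synthetic input file set for one case template.

    Produces clinical YAML, expression TSV (tumor + 3 controls), somatic and
    germline VCFs, a SEG file, a methylation table and a manifest JSON
    listing every plant; returns the manifest.
    """
    kb = kb or load_knowledge_base()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    panel = gene_panel(n_genes, kb)

    mu = np.full(len(panel), BASELINE)
    controls = _control_matrix(mu)
    tumor = mu + rng.normal(0, 1.0, len(panel))
    # case tumors carry the broad transcriptional program of their subtype
    # (fillers only, so exact marker plants below stay untouched)
    program = {"case2_tamoxifen": "luminal A", "case3_immuno": "basal-like"}
    if spec.template in program:
        shift = _subtype_centroid(program[spec.template], panel)
        fillers = np.array([g.startswith("SYN") for g in panel])
        tumor[fillers] += shift[fillers]
    plants = _case_expression_plants(spec.template)
    idx = {g: i for i, g in enumerate(panel)}
    for g, z in plants.items():
        tumor[idx[g]] = mu[idx[g]] + z  # controls have sd exactly 1 -> z is exact

    clinical = _case_clinical(spec.template)
    somatic, germline = _case_variants(spec.template, kb, rng)
    segments = _case_segments(spec.template, rng, kb)
    methylation = _case_methylation(panel, spec.template, rng)

    files = {
        "clinical": str(outdir / "clinical.yaml"),
        "expression": str(outdir / "expression.tsv"),
        "somatic_vcf": str(outdir / "somatic.vcf"),
        "germline_vcf": str(outdir / "germline.vcf"),
        "seg": str(outdir / "segments.seg"),
        "methylation": str(outdir / "methylation.tsv"),
    }
    write_clinical(clinical, files["clinical"])
    write_expression(ExpressionTable(panel, tumor, controls), files["expression"])
    write_vcf(somatic, files["somatic_vcf"], CONTIGS)
    write_vcf(germline, files["germline_vcf"], CONTIGS)
    write_seg(segments, files["seg"], sample=clinical.patient_id)
    write_methylation(methylation, files["methylation"])

    manifest = {
        "template": spec.template,
        "seed": spec.seed,
        "patient_id": clinical.patient_id,
        "n_genes": len(panel),
        "exome_mb": exome_megabases(kb),
        "files": files,
        "plants": {
            "expression_z": plants,
            "somatic_variants": [
                {"gene": m.gene_id, "consequence": m.consequence, "impact": m.impact,
                 "chrom": m.chrom, "pos": m.pos} for m in somatic],
            "germline_variants": [
                {"gene": m.gene_id, "consequence": m.consequence, "impact": m.impact,
                 "chrom": m.chrom, "pos": m.pos} for m in germline],
            "n_somatic_exonic": len({(m.chrom, m.pos, m.ref, m.alt) for m in somatic}),
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
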