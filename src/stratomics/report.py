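"""Pipeline orchestration and the consolidated JSON report.

``run_pipeline`` wires the stages together: input parsing and harmonization,
driver prioritization, pathway activities, subtype call, drug assessment and
the immunotherapy section. Stages whose inputs are absent are marked
``skipped`` rather than failing, so partial uploads still yield a report.
The report is deterministic given inputs and configuration (all stochastic
stages are seeded) and records the knowledge-bundle content hash plus every
run parameter; visualization outputs are data exports, not images.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd

from . import __version__
from .bundle import OmicsBundle, assemble_bundle
from .clinical import read_clinical
from .drivers import DriverEvent, map_segments_to_genes, prioritize_drivers
from .drugrules import assess_driver_targeting, assess_soc, check_consistency
from .errors import InputError
from .expression import read_expression, compute_deregulation
from .immuno import (compute_tmb, tmb_percentile, repair_gene_status,
                     checkpoint_overview, export_tmb_plot_data)
from .knowledge import KnowledgeBundle, load_knowledge_base
from .methylation import read_methylation, compute_methylation_diff, MethylationTable
from .pathways import (score_pathways, activity_vector, rank_similar_samples,
                       export_radar, ActivityVector, DEFAULT_N_PERM, DEFAULT_SEED)
from .segments import read_seg
from .subtyping import ReferenceCohort, call_subtype, embed
from .synthetic import CohortSpec, generate_cohort, exome_megabases
from .variants import read_vcf


@dataclass
class RunConfig:
    clinical: str
    expression: Optional[str] = None
    somatic_vcf: Optional[str] = None
    germline_vcf: Optional[str] = None
    seg: Optional[str] = None
    methylation: Optional[str] = None
    knowledge_root: Optional[str] = None
    cohort_expression: Optional[str] = None
    cohort_labels: Optional[str] = None
    cohort_activities: Optional[str] = None
    cohort_tmb: Optional[str] = None
    seed: int = DEFAULT_SEED
    n_perm: int = DEFAULT_N_PERM
    exome_mb: Optional[float] = None    # default: toy-genome exonic territory
    outdir: Optional[str] = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = set(cls.__dataclass_fields__)
        extra = set(raw) - known
        if extra:
            raise InputError(f"{path}: unknown config keys {sorted(extra)}")
        return cls(**raw)


def _load_cohort(config: RunConfig, kb: KnowledgeBundle) -> ReferenceCohort:
    if config.cohort_expression and config.cohort_labels:
        cohort = ReferenceCohort.from_files(config.cohort_expression, config.cohort_labels,
                                            config.cohort_activities)
        if config.cohort_tmb:
            tmb = pd.read_csv(config.cohort_tmb, sep="\t", index_col=0).iloc[:, 0]
            cohort.tmb_values = tmb.to_dict()
        return cohort
    return generate_cohort(CohortSpec(seed=config.seed), kb)


def run_pipeline(config: RunConfig, cohort: Optional[ReferenceCohort] = None) -> dict:
    """Execute all stages and return the consolidated report dictionary."""
    kb = load_knowledge_base(config.knowledge_root)
    clinical = read_clinical(config.clinical)

    dereg = None
    if config.expression:
        dereg = compute_deregulation(read_expression(config.expression))
    mutations = []
    if config.somatic_vcf:
        mutations += read_vcf(config.somatic_vcf, "somatic")
    if config.germline_vcf:
        mutations += read_vcf(config.germline_vcf, "germline")
    segments = read_seg(config.seg) if config.seg else None
    methylation_diff = None
    if config.methylation:
        meth = read_methylation(config.methylation)
        scores = (meth if not isinstance(meth, MethylationTable)
                  else compute_methylation_diff(meth))
        methylation_diff = scores.scores

    cna_calls = map_segments_to_genes(segments, kb.gene_models) if segments else []
    bundle = assemble_bundle(
        clinical, deregulation=dereg, mutations=mutations or None,
        cna={c.gene_id: c.log_ratio for c in cna_calls} or None,
        methylation_diff=methylation_diff,
        provenance={k: str(v) for k, v in (
            ("expression", config.expression), ("somatic_vcf", config.somatic_vcf),
            ("germline_vcf", config.germline_vcf), ("seg", config.seg),
            ("methylation", config.methylation)) if v})

    report: Dict[str, object] = {
        "tool": {"name": "stratomics", "version": __version__,
                 "knowledge_hash": kb.content_hash},
        "run_parameters": {"seed": config.seed, "n_perm": config.n_perm,
                           "exome_mb": config.exome_mb or exome_megabases(kb)},
        "clinical": clinical.to_dict(),
        "skipped": [],
    }
    skipped: List[str] = report["skipped"]  # type: ignore[assignment]

    # driver events
    if bundle.genes():
        events = prioritize_drivers(bundle, kb.driver_catalog, cna_calls)
        report["drivers"] = [
            {"gene_id": e.gene_id, "channels": e.channels, "severity_grade": e.severity_grade,
             "priority_score": e.priority_score, "details": e.details} for e in events]
    else:
        skipped.append("drivers")

    # pathway activities
    activities = []
    if dereg is not None:
        activities = score_pathways(dereg, kb, n_perm=config.n_perm, seed=config.seed)
        report["pathways"] = [r.to_dict() for r in activities]
    else:
        skipped.append("pathways")

    # subtype call + similarity ranking
    if dereg is not None or config.expression:
        if cohort is None:
            cohort = _load_cohort(config, kb)
        expr = read_expression(config.expression)
        query = dict(zip(expr.genes, expr.tumor))
        label, votes = call_subtype(query, cohort)
        report["subtype"] = {"call": label, "vote_fractions": votes}
        if activities and cohort.activity_matrix is not None:
            qvec = activity_vector(clinical.patient_id, activities)
            refs = [ActivityVector(s, list(cohort.activity_matrix.columns),
                                   cohort.activity_matrix.loc[s].to_numpy())
                    for s in cohort.activity_matrix.index]
            ranked = rank_similar_samples(qvec, refs)
            report["similar_samples"] = [
                {"sample_id": s, "distance": d, "subtype": cohort.labels.get(s)}
                for s, d in ranked[:10]]
    else:
        skipped.append("subtype")

    # drug assessment
    soc = assess_soc(kb.soc_drugs, bundle, activities)
    targeting = assess_driver_targeting(kb.driver_targeting_drugs, bundle, activities)
    warnings = check_consistency(bundle, cna_calls)
    report["drugs"] = {
        "soc": [a.to_dict() for a in soc],
        "off_label": [a.to_dict() for a in targeting],
        "consistency_warnings": warnings,
    }

    # immunotherapy section
    if mutations:
        exome_mb = config.exome_mb or exome_megabases(kb)
        tmb = compute_tmb(mutations, exome_mb, exon_intervals=kb.gene_models)
        if cohort is None and (config.cohort_tmb or not config.cohort_expression):
            cohort = _load_cohort(config, kb)
        if cohort is not None and cohort.tmb_values:
            tmb.cohort_percentile = tmb_percentile(tmb.tmb, list(cohort.tmb_values.values()))
        repair = repair_gene_status(bundle, kb.gene_list("dna_repair"))
        checkpoints = checkpoint_overview(bundle, kb.gene_list("checkpoint_biomarkers"),
                                          {c.gene_id: c for c in cna_calls})
        report["immuno"] = {
            "tmb": tmb.to_dict(),
            "tmb_counts_exonic_only": True,
            "repair_genes": [{"gene_id": r.gene_id, "best_grade": r.best_grade,
                              "impaired": r.impaired} for r in repair],
            "checkpoint_biomarkers": checkpoints.where(pd.notna(checkpoints), None)
                                                .to_dict(orient="records"),
            "neoepitope_note": "neoepitope prediction and HLA typing are external steps "
                               "not performed by this package",
        }
    else:
        skipped.append("immuno")

    validate_report(report)
    if config.outdir:
        write_exports(report, bundle, kb, activities, cohort, config)
    return report


_REQUIRED_SECTIONS = ("tool", "run_parameters", "clinical", "drugs", "skipped")


def validate_report(report: dict) -> None:
    """Structural validation; fatal on missing sections or malformed entries."""
    for key in _REQUIRED_SECTIONS:
        if key not in report:
            raise InputError(f"report: missing section {key!r}")
    for section in ("drivers", "pathways", "subtype", "immuno"):
        if section not in report and section not in report["skipped"]:
            raise InputError(f"report: section {section!r} neither present nor skipped")
    for assessment in report["drugs"]["soc"] + report["drugs"]["off_label"]:
        if assessment["verdict"] not in ("suggested", "conditional", "contraindicated",
                                         "not_assessable"):
            raise InputError(f"report: bad verdict {assessment['verdict']!r}")


def export_sunburst(report: dict, kb: KnowledgeBundle, path=None) -> dict:
    """Hierarchical pathway->gene export mirroring the ring overview.

    Each gene is attached to the member pathway where its |weight| is largest
    (ties to the lexicographically smallest pathway id). Per-gene ring values:
    deregulation, methylation, CNA, mutation grade, oncogene/TSG role and
    druggability.
    """
    assignment: Dict[str, str] = {}
    best_weight: Dict[str, float] = {}
    for pw in sorted(kb.pathways, key=lambda p: p.pathway_id):
        for gene, weight, _ in pw.members:
            if gene not in assignment or abs(weight) > best_weight[gene]:
                assignment[gene] = pw.pathway_id
                best_weight[gene] = abs(weight)
    druggable = {item.subject for drug in kb.soc_drugs + kb.driver_targeting_drugs
                 for item in drug.rule_items if item.kind == "target"}
    catalog = {e.gene_id: e.role for e in kb.driver_catalog}
    pathway_info = {p["pathway_id"]: p for p in report.get("pathways", [])}
    driver_details = {d["gene_id"]: d for d in report.get("drivers", [])}

    rings = []
    for pw in kb.pathways:
        genes = []
        for gene, _, _ in pw.members:
            if assignment[gene] != pw.pathway_id:
                continue
            detail = driver_details.get(gene, {}).get("details", {})
            genes.append({
                "gene_id": gene,
                "expression": detail.get("deregulation"),
                "methylation": detail.get("methylation_diff"),
                "cna": detail.get("cna_log_ratio"),
                "mutation": driver_details.get(gene, {}).get("severity_grade"),
                "role": catalog.get(gene),
                "druggable": gene in druggable,
            })
        info = pathway_info.get(pw.pathway_id, {})
        rings.append({"pathway_id": pw.pathway_id, "display_name": pw.display_name,
                      "activity": info.get("activity"), "label": info.get("label"),
                      "genes": genes})
    data = {"rings": rings}
    if path is not None:
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1)
    return data


def write_exports(report: dict, bundle: OmicsBundle, kb: KnowledgeBundle,
                  activities, cohort: Optional[ReferenceCohort],
                  config: RunConfig) -> None:
    """Write report.json plus all visualization data exports."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    if activities:
        export_radar(activities, path=outdir / "radar.json")
    export_sunburst(report, kb, path=outdir / "sunburst.json")
    if "immuno" in report and cohort is not None and cohort.tmb_values:
        from .immuno import TMBResult
        t = report["immuno"]["tmb"]
        export_tmb_plot_data(TMBResult(**t), list(cohort.tmb_values.values()),
                             path=outdir / "tmb.json")
    if "drivers" in report:
        pd.DataFrame([{k: (",".join(d[k]) if k == "channels" else d[k])
                       for k in ("gene_id", "channels", "severity_grade", "priority_score")}
                      for d in report["drivers"]]).to_csv(
            outdir / "drivers.tsv", sep="\t", index=False)
    rows = []
    for a in report["drugs"]["soc"] + report["drugs"]["off_label"]:
        rows.append({"drug_id": a["drug_id"], "category": a["category"],
                     "verdict": a["verdict"], "n_supporting": a["n_supporting"],
                     "n_contra": a["n_contra"]})
    pd.DataFrame(rows).to_csv(outdir / "drugs.tsv", sep="\t", index=False)
    if cohort is not None and config.expression:
        expr = read_expression(config.expression)
        query = dict(zip(expr.genes, expr.tumor))
        for method in ("pca", "tsne"):
            emb = embed(query, cohort, method=method, seed=config.seed,
                        query_id=report["clinical"]["patient_id"])
            emb.to_json(outdir / f"embedding_{method}.json")
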