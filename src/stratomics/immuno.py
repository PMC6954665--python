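"""Immunotherapy biomarkers: tumor mutational burden, DNA-repair gene status
and checkpoint-inhibitor biomarker overview.

TMB is the number of somatic mutations per megabase of exonic territory.
High TMB and impaired DNA repair are associated with response to checkpoint
blockade; the cohort percentile contextualizes the value the way a cohort
waterfall plot would. Neoepitope prediction and HLA typing are external
steps; the report reserves a section noting them.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .bundle import OmicsBundle
from .drivers import best_grade, grade_mutation
from .errors import InputError
from .knowledge import GeneListResource, GeneModel
from .pathways import midrank_position
from .variants import MutationRecord

DEFAULT_EXOME_MB = 30.0


@dataclass
class TMBResult:
    n_somatic: int
    exome_mb: float
    tmb: float
    cohort_percentile: Optional[float] = None
    log10_tmb: Optional[float] = None

    def to_dict(self) -> dict:
        return {"n_somatic": self.n_somatic, "exome_mb": self.exome_mb, "tmb": self.tmb,
                "cohort_percentile": self.cohort_percentile, "log10_tmb": self.log10_tmb}


@dataclass
class RepairStatusEntry:
    gene_id: str
    best_grade: str
    impaired: bool


def compute_tmb(mutations: Sequence[MutationRecord], exome_mb: float = DEFAULT_EXOME_MB,
                exon_intervals: Optional[Sequence[GeneModel]] = None) -> TMBResult:
    """Somatic mutation count per megabase exon.

    Duplicate variants (same chrom/pos/ref/alt) count once. When exon
    intervals are given, only somatic variants falling inside one are counted.
    """
    if exome_mb <= 0:
        raise InputError("compute_tmb: exome_mb must be positive")
    if mutations and not all(m.origin in ("somatic", "germline") for m in mutations):
        raise InputError("compute_tmb: cannot derive somatic set without origin labels")
    seen = set()
    n = 0
    for m in mutations:
        if m.origin != "somatic":
            continue
        key = (m.chrom, m.pos, m.ref, m.alt)
        if key in seen:
            continue
        seen.add(key)
        if exon_intervals is not None:
            pos0 = m.pos - 1  # VCF 1-based -> 0-based half-open
            if not any(iv.chrom == m.chrom and iv.start <= pos0 < iv.end
                       for iv in exon_intervals):
                continue
        n += 1
    tmb = n / exome_mb
    return TMBResult(n, exome_mb, tmb, log10_tmb=math.log10(tmb) if tmb > 0 else None)


def tmb_percentile(tmb: float, cohort_tmbs: Sequence[float]) -> float:
    """Midrank percentile of a TMB value within the cohort TMB vector."""
    cohort = np.asarray(cohort_tmbs, dtype=float)
    if cohort.size == 0:
        raise InputError("tmb_percentile: empty cohort")
    return 100.0 * midrank_position(tmb, cohort)


def repair_gene_status(bundle: OmicsBundle, repair_list: GeneListResource
                       ) -> List[RepairStatusEntry]:
    """Impairment summary per DNA-repair gene (impaired iff severe/damaging)."""
    entries = []
    for gene in sorted(repair_list.members):
        grade = best_grade(bundle.mutations_for(gene))
        entries.append(RepairStatusEntry(gene, grade, grade in ("severe", "damaging")))
    return entries


def checkpoint_overview(bundle: OmicsBundle, checkpoint_list: GeneListResource,
                        cna_calls: Optional[Dict[str, object]] = None) -> pd.DataFrame:
    """Per-gene (epi-)genomic and transcriptomic status of checkpoint biomarkers."""
    rows = []
    cna_calls = cna_calls or {}
    for gene in sorted(checkpoint_list.members):
        call = cna_calls.get(gene)
        rows.append({
            "gene_id": gene,
            "deregulation": bundle.deregulation.get(gene) if bundle.deregulation else None,
            "cna_log_ratio": getattr(call, "log_ratio", None),
            "methylation_diff": bundle.methylation_diff.get(gene),
            "mutation_grade": best_grade(bundle.mutations_for(gene)),
        })
    return pd.DataFrame(rows)


def export_tmb_plot_data(result: TMBResult, cohort_tmbs: Sequence[float],
                         n_bins: int = 20, path=None) -> dict:
    """Cohort histogram plus per-sample log10 values for a waterfall plot."""
    cohort = np.sort(np.asarray(cohort_tmbs, dtype=float))
    hist, edges = np.histogram(cohort, bins=n_bins)
    data = {
        "query": result.to_dict(),
        "histogram": {"counts": hist.tolist(), "bin_edges": edges.tolist()},
        "cohort_sorted_tmb": cohort.tolist(),
        "cohort_sorted_log10_tmb": [math.log10(t) if t > 0 else None for t in cohort],
    }
    if path is not None:
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1)
    return data
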