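"""Driver event identification and mutation severity grading.

Severity grading follows the annotation conventions of the upstream effect
predictors: HIGH-impact consequences (stop gain, frameshift, splice site)
are *severe*; MODERATE-impact variants with SIFT < 0.05 or PolyPhen > 0.85
are *damaging*; remaining MODERATE variants are *moderate*; LOW impact is
*low*; everything else *unknown*.

A catalog gene becomes a driver event when at least one channel is altered:
a mutation graded moderate or worse, a non-neutral copy-number call, strong
differential methylation, or strong expression deregulation. The priority
score is an explicit surrogate (the published tool does not print one):

    priority = catalog_weight * severity_points + (n_altered_channels - 1)

with severity points severe=3, damaging=2, moderate=1.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .bundle import OmicsBundle
from .errors import InputError
from .knowledge import DriverCatalogEntry, GeneModel
from .segments import SegmentRecord
from .variants import MutationRecord

SEVERITY_ORDER = ("unknown", "low", "moderate", "damaging", "severe")
SEVERITY_POINTS = {"severe": 3, "damaging": 2, "moderate": 1}
AMP_THRESHOLD = 0.3
DEL_THRESHOLD = -0.3
METHYLATION_THRESHOLD = 1.0
DEREGULATION_THRESHOLD = 2.0
SIFT_DELETERIOUS = 0.05
POLYPHEN_DAMAGING = 0.85


@dataclass
class GeneCnaCall:
    gene_id: str
    log_ratio: float
    call: str  # amplified | deleted | neutral


@dataclass
class DriverEvent:
    gene_id: str
    channels: List[str]
    severity_grade: str
    priority_score: float
    details: Dict[str, object] = field(default_factory=dict)


def grade_mutation(m: MutationRecord) -> str:
    if m.impact == "HIGH":
        return "severe"
    if m.impact == "MODERATE":
        if (m.sift is not None and m.sift < SIFT_DELETERIOUS) or \
           (m.polyphen is not None and m.polyphen > POLYPHEN_DAMAGING):
            return "damaging"
        return "moderate"
    if m.impact == "LOW":
        return "low"
    return "unknown"


def best_grade(mutations: Sequence[MutationRecord]) -> str:
    """Most severe grade among a gene's mutations ('unknown' when empty)."""
    if not mutations:
        return "unknown"
    return max((grade_mutation(m) for m in mutations), key=SEVERITY_ORDER.index)


def map_segments_to_genes(segments: Sequence[SegmentRecord], models: Sequence[GeneModel],
                          amp_threshold: float = AMP_THRESHOLD,
                          del_threshold: float = DEL_THRESHOLD) -> List[GeneCnaCall]:
    """Per-gene log-ratio as the length-weighted mean of overlapping segments
    (0-based half-open arithmetic); genes without overlap are omitted."""
    by_chrom: Dict[str, List[SegmentRecord]] = {}
    for s in segments:
        by_chrom.setdefault(s.chrom, []).append(s)
    calls: List[GeneCnaCall] = []
    for gm in models:
        total = weighted = 0.0
        for s in by_chrom.get(gm.chrom, []):
            ov = min(gm.end, s.end) - max(gm.start, s.start)
            if ov > 0:
                total += ov
                weighted += ov * s.log_ratio
        if total == 0:
            continue
        lr = weighted / total
        call = ("amplified" if lr >= amp_threshold
                else "deleted" if lr <= del_threshold else "neutral")
        calls.append(GeneCnaCall(gm.gene_id, lr, call))
    return calls


def cna_call_map(calls: Sequence[GeneCnaCall]) -> Dict[str, GeneCnaCall]:
    return {c.gene_id: c for c in calls}


def altered_channels(bundle: OmicsBundle, gene: str,
                     cna_calls: Optional[Dict[str, GeneCnaCall]] = None,
                     methylation_threshold: float = METHYLATION_THRESHOLD,
                     deregulation_threshold: float = DEREGULATION_THRESHOLD
                     ) -> Tuple[List[str], str]:
    """Channels with a qualifying alteration for one gene, plus mutation grade."""
    channels: List[str] = []
    grade = best_grade(bundle.mutations_for(gene))
    if SEVERITY_ORDER.index(grade) >= SEVERITY_ORDER.index("moderate"):
        channels.append("mutation")
    cna_calls = cna_calls if cna_calls is not None else {}
    call = cna_calls.get(gene)
    if call is not None and call.call != "neutral":
        channels.append("cna")
    meth = bundle.methylation_diff.get(gene)
    if meth is not None and abs(meth) >= methylation_threshold:
        channels.append("methylation")
    dereg = bundle.deregulation.get(gene) if bundle.deregulation else None
    if dereg is not None and abs(dereg) >= deregulation_threshold:
        channels.append("expression")
    return channels, grade


def prioritize_drivers(bundle: OmicsBundle, catalog: Sequence[DriverCatalogEntry],
                       cna_calls: Optional[Sequence[GeneCnaCall]] = None
                       ) -> List[DriverEvent]:
    """Ordered driver events for catalog genes with >=1 altered channel."""
    calls = cna_call_map(cna_calls or [])
    events: List[DriverEvent] = []
    for entry in catalog:
        channels, grade = altered_channels(bundle, entry.gene_id, calls)
        if not channels:
            continue
        points = SEVERITY_POINTS.get(grade, 0)
        score = entry.priority_weight * points + (len(channels) - 1)
        details: Dict[str, object] = {"catalog_role": entry.role,
                                      "catalog_weight": entry.priority_weight}
        muts = bundle.mutations_for(entry.gene_id)
        if muts:
            details["mutations"] = [
                {"consequence": m.consequence, "impact": m.impact, "origin": m.origin,
                 "sift": m.sift, "polyphen": m.polyphen, "grade": grade_mutation(m)}
                for m in muts]
        if entry.gene_id in calls:
            details["cna_log_ratio"] = calls[entry.gene_id].log_ratio
            details["cna_call"] = calls[entry.gene_id].call
        if bundle.deregulation and bundle.deregulation.get(entry.gene_id) is not None:
            details["deregulation"] = bundle.deregulation.scores[entry.gene_id]
        if entry.gene_id in bundle.methylation_diff:
            details["methylation_diff"] = bundle.methylation_diff[entry.gene_id]
        events.append(DriverEvent(entry.gene_id, channels, grade, score, details))
    return sorted(events, key=lambda e: (-e.priority_score, e.gene_id))
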