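"""The harmonized per-gene multi-omics view of one tumor sample.

``assemble_bundle`` re-keys every channel (deregulation, mutations, CNA,
methylation) into the unified identifier namespace, validates cross-channel
consistency and attaches per-channel provenance descriptors. At least one
omics channel must be present.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

from .clinical import ClinicalRecord
from .errors import InputError
from .expression import DeregulationScores
from .identifiers import IdentifierMap, map_identifiers, load_default_map
from .variants import MutationRecord, group_by_gene


@dataclass
class OmicsBundle:
    clinical: ClinicalRecord
    deregulation: Optional[DeregulationScores] = None
    mutations: Dict[str, List[MutationRecord]] = field(default_factory=dict)
    cna: Dict[str, float] = field(default_factory=dict)
    methylation_diff: Dict[str, float] = field(default_factory=dict)
    provenance: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if (self.deregulation is None and not self.mutations
                and not self.cna and not self.methylation_diff):
            raise InputError("omics bundle: at least one omics channel is required")

    def genes(self) -> set:
        out = set(self.mutations) | set(self.cna) | set(self.methylation_diff)
        if self.deregulation is not None:
            out |= set(self.deregulation.scores)
        return out

    def mutations_for(self, gene: str) -> List[MutationRecord]:
        return self.mutations.get(gene, [])


def _remap_scores(scores: DeregulationScores, mapping: IdentifierMap) -> DeregulationScores:
    id_map = map_identifiers(list(scores.scores), mapping)
    remapped: Dict[str, float] = {}
    for gene, value in scores.scores.items():
        remapped[id_map[gene]] = value
    flagged = [id_map[g] for g in scores.flagged_genes]
    return DeregulationScores(remapped, scores.score_kind, flagged)


def _remap_dict(d: Dict[str, float], mapping: IdentifierMap) -> Dict[str, float]:
    if not d:
        return {}
    id_map = map_identifiers(list(d), mapping)
    return {id_map[k]: v for k, v in d.items()}


def assemble_bundle(clinical: ClinicalRecord,
                    deregulation: Optional[DeregulationScores] = None,
                    mutations: Optional[List[MutationRecord]] = None,
                    cna: Optional[Dict[str, float]] = None,
                    methylation_diff: Optional[Dict[str, float]] = None,
                    mapping: Optional[IdentifierMap] = None,
                    provenance: Optional[Dict[str, str]] = None) -> OmicsBundle:
    """Harmonize all provided channels into one gene-keyed bundle."""
    mapping = mapping or load_default_map()
    grouped: Dict[str, List[MutationRecord]] = {}
    if mutations:
        raw = group_by_gene(mutations)
        if raw:
            id_map = map_identifiers(list(raw), mapping)
            for gene, recs in raw.items():
                grouped.setdefault(id_map[gene], []).extend(recs)
    bundle = OmicsBundle(
        clinical=clinical,
        deregulation=_remap_scores(deregulation, mapping) if deregulation else None,
        mutations=grouped,
        cna=_remap_dict(cna or {}, mapping),
        methylation_diff=_remap_dict(methylation_diff or {}, mapping),
        provenance=dict(provenance or {}),
    )
    return bundle
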