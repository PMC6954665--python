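"""Declarative knowledge bundle: pathway gene sets, driver catalog, drug
rules, curated gene lists and the miniature gene models used for CNA mapping.

The default bundle ships with the package and is validated on load: exactly
20 pathways, 17 standard-of-care drugs and 23 driver-targeting drugs, closed
predicate vocabulary, every referenced gene resolvable in the identifier
cross-reference. A SHA-256 content hash over all bundle files is recorded so
reports can state exactly which knowledge they were produced with.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import pandas as pd
import yaml

from .errors import InputError

N_PATHWAYS = 20
N_SOC_DRUGS = 17
N_DRIVER_TARGETING_DRUGS = 23

PREDICATES = (
    "status_equals", "expression_above", "expression_below", "lof_mutation_present",
    "any_mutation_present", "severity_at_most", "activity_label_in",
    "copy_number_above", "mutation_absent",
)
RULE_KINDS = ("biomarker", "target", "metabolizing_enzyme", "efflux_transporter",
              "pathway", "genomic_marker")
DIRECTIONS = ("supports", "contraindicates")
DRIVER_ROLES = ("oncogene", "tumor_suppressor", "ambiguous")
GENE_LIST_IDS = ("dna_repair", "checkpoint_biomarkers", "efflux_transporters",
                 "drug_metabolizing_enzymes")

_FILES = ("pathways.gmt", "drugs_soc.yaml", "drugs_driver_targeting.yaml",
          "driver_catalog.tsv", "gene_lists.yaml", "gene_models.bed", "id_map.tsv")


@dataclass
class PathwayDefinition:
    pathway_id: str
    display_name: str
    members: List[tuple]  # (gene_id, weight, role)

    def __post_init__(self):
        if len(self.members) < 3:
            raise InputError(f"pathway {self.pathway_id}: needs >=3 members")
        weights = [w for _, w, _ in self.members]
        if not all(abs(w) < float("inf") for w in weights) or all(w == 0 for w in weights):
            raise InputError(f"pathway {self.pathway_id}: weights must be finite, not all zero")
        for _, _, role in self.members:
            if role not in ("activator", "inhibitor"):
                raise InputError(f"pathway {self.pathway_id}: role {role!r}")

    def signed_weights(self) -> Dict[str, float]:
        """Member weights with inhibitor sign folded in."""
        return {g: (w if role == "activator" else -w) for g, w, role in self.members}


@dataclass
class DriverCatalogEntry:
    gene_id: str
    role: str
    priority_weight: float
    source_tag: str

    def __post_init__(self):
        if self.role not in DRIVER_ROLES:
            raise InputError(f"driver catalog {self.gene_id}: role {self.role!r}")
        if self.priority_weight <= 0:
            raise InputError(f"driver catalog {self.gene_id}: non-positive weight")


@dataclass
class RuleItem:
    kind: str
    subject: str
    predicate: str
    threshold: object
    direction: str
    evidence_ref: str
    decisive: bool = True   # biomarker/enzyme items may opt out of being verdict gates

    def __post_init__(self):
        if self.kind not in RULE_KINDS:
            raise InputError(f"rule item: unknown kind {self.kind!r}")
        if self.predicate not in PREDICATES:
            raise InputError(f"rule item: unknown predicate {self.predicate!r}")
        if self.direction not in DIRECTIONS:
            raise InputError(f"rule item: unknown direction {self.direction!r}")
        if not self.evidence_ref:
            raise InputError("rule item: evidence_ref must be non-empty")


@dataclass
class DrugRule:
    drug_id: str
    drug_name: str
    category: str
    rule_items: List[RuleItem]
    curation: str = "placeholder"

    def __post_init__(self):
        if self.category not in ("soc", "driver_targeting"):
            raise InputError(f"drug {self.drug_id}: category {self.category!r}")
        if not self.rule_items:
            raise InputError(f"drug {self.drug_id}: needs >=1 rule item")


@dataclass
class GeneListResource:
    list_id: str
    members: List[str]

    def __post_init__(self):
        if self.list_id not in GENE_LIST_IDS:
            raise InputError(f"gene list: unknown list_id {self.list_id!r}")
        if not self.members:
            raise InputError(f"gene list {self.list_id}: empty")


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    start: int      # 0-based half-open internally
    end: int

    def __post_init__(self):
        if self.start >= self.end:
            raise InputError(f"gene model {self.gene_id}: start >= end")


@dataclass
class KnowledgeBundle:
    pathways: List[PathwayDefinition]
    driver_catalog: List[DriverCatalogEntry]
    soc_drugs: List[DrugRule]
    driver_targeting_drugs: List[DrugRule]
    gene_lists: Dict[str, GeneListResource]
    gene_models: List[GeneModel]
    content_hash: str = ""
    root: Optional[Path] = None
    _models_by_gene: Dict[str, GeneModel] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self._models_by_gene = {m.gene_id: m for m in self.gene_models}

    def pathway(self, pathway_id: str) -> Optional[PathwayDefinition]:
        return next((p for p in self.pathways if p.pathway_id == pathway_id), None)

    def gene_list(self, list_id: str) -> GeneListResource:
        return self.gene_lists[list_id]

    def model_for(self, gene_id: str) -> Optional[GeneModel]:
        return self._models_by_gene.get(gene_id)

    def catalog_entry(self, gene_id: str) -> Optional[DriverCatalogEntry]:
        return next((e for e in self.driver_catalog if e.gene_id == gene_id), None)


def default_knowledge_root() -> Path:
    ref = resources.files("stratomics.data.knowledge")
    return Path(str(ref))


def _load_pathways(path: Path) -> List[PathwayDefinition]:
    pathways = []
    for n, line in enumerate(path.read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise InputError(f"{path}: line {n}: GMT needs id, description, members")
        members = []
        for token in parts[2:]:
            try:
                gene, weight, role = token.split("|")
                members.append((gene, float(weight), role))
            except ValueError as exc:
                raise InputError(f"{path}: line {n}: bad member token {token!r}") from exc
        pathways.append(PathwayDefinition(parts[0], parts[1], members))
    return pathways


def _load_drugs(path: Path, expect_category: str) -> List[DrugRule]:
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict) or "drugs" not in raw:
        raise InputError(f"{path}: expected a mapping with a 'drugs' list")
    category = raw.get("category", expect_category)
    if category != expect_category:
        raise InputError(f"{path}: category {category!r}, expected {expect_category!r}")
    drugs = []
    for d in raw["drugs"]:
        try:
            items = [RuleItem(**item) for item in d.get("rule_items", [])]
            drugs.append(DrugRule(d["drug_id"], d.get("drug_name", d["drug_id"]),
                                  category, items, d.get("curation", "placeholder")))
        except (KeyError, TypeError) as exc:
            raise InputError(f"{path}: drug entry {d.get('drug_id', '?')}: {exc}") from exc
        except InputError as exc:
            raise InputError(f"{path}: {exc}") from exc
    return drugs


def _load_gene_lists(path: Path) -> Dict[str, GeneListResource]:
    raw = yaml.safe_load(path.read_text())
    lists = raw.get("lists") if isinstance(raw, dict) else None
    if not isinstance(lists, dict):
        raise InputError(f"{path}: expected a mapping with a 'lists' section")
    out = {}
    for list_id, members in lists.items():
        if list_id in out:
            raise InputError(f"{path}: duplicate gene list {list_id!r}")
        out[list_id] = GeneListResource(list_id, list(members))
    return out


def _load_gene_models(path: Path) -> List[GeneModel]:
    df = pd.read_csv(path, sep="\t", comment="#")
    models = []
    for _, row in df.iterrows():
        # BED-like fixture is 1-based inclusive; convert to 0-based half-open
        models.append(GeneModel(str(row["gene_id"]), str(row["chrom"]),
                                int(row["start"]) - 1, int(row["end"])))
    return models


def load_knowledge_base(root: Optional[Path] = None) -> KnowledgeBundle:
    """Load and validate a knowledge directory; the packaged bundle by default."""
    root = Path(root) if root is not None else default_knowledge_root()
    for fname in _FILES:
        if not (root / fname).exists():
            raise InputError(f"knowledge bundle {root}: missing file {fname}")

    pathways = _load_pathways(root / "pathways.gmt")
    if len(pathways) != N_PATHWAYS:
        raise InputError(f"{root / 'pathways.gmt'}: expected {N_PATHWAYS} pathways, "
                         f"found {len(pathways)}")
    soc = _load_drugs(root / "drugs_soc.yaml", "soc")
    if len(soc) != N_SOC_DRUGS:
        raise InputError(f"{root / 'drugs_soc.yaml'}: expected {N_SOC_DRUGS} drugs, "
                         f"found {len(soc)}")
    targeting = _load_drugs(root / "drugs_driver_targeting.yaml", "driver_targeting")
    if len(targeting) != N_DRIVER_TARGETING_DRUGS:
        raise InputError(f"{root / 'drugs_driver_targeting.yaml'}: expected "
                         f"{N_DRIVER_TARGETING_DRUGS} drugs, found {len(targeting)}")

    catalog_df = pd.read_csv(root / "driver_catalog.tsv", sep="\t", comment="#")
    catalog = [DriverCatalogEntry(str(r.gene_id), str(r.role), float(r.priority_weight),
                                  str(r.source_tag)) for r in catalog_df.itertuples()]
    if len({e.gene_id for e in catalog}) != len(catalog):
        raise InputError(f"{root / 'driver_catalog.tsv'}: duplicate gene entries")

    gene_lists = _load_gene_lists(root / "gene_lists.yaml")
    gene_models = _load_gene_models(root / "gene_models.bed")

    # every referenced gene must resolve in the cross-reference
    xref = pd.read_csv(root / "id_map.tsv", sep="\t", comment="#")
    known = set(xref["hgnc"].astype(str))
    referenced = {g for p in pathways for g, _, _ in p.members}
    referenced |= {e.gene_id for e in catalog}
    for drug in soc + targeting:
        for item in drug.rule_items:
            if item.kind in ("target", "metabolizing_enzyme", "efflux_transporter",
                             "genomic_marker"):
                referenced.add(item.subject)
    for res in gene_lists.values():
        referenced |= set(res.members)
    unresolved = sorted(referenced - known)
    if unresolved:
        raise InputError(f"knowledge bundle {root}: genes without cross-reference: "
                         f"{unresolved[:10]}")
    pathway_ids = {p.pathway_id for p in pathways}
    for drug in soc + targeting:
        for item in drug.rule_items:
            if item.kind == "pathway" and item.subject not in pathway_ids:
                raise InputError(f"drug {drug.drug_id}: unknown pathway {item.subject!r}")

    digest = hashlib.sha256()
    for fname in _FILES:
        digest.update(fname.encode())
        digest.update((root / fname).read_bytes())
    return KnowledgeBundle(pathways, catalog, soc, targeting, gene_lists, gene_models,
                           content_hash=digest.hexdigest(), root=root)
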