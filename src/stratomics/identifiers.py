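"""Gene identifier harmonization.

All omics channels are re-keyed to a single namespace (HGNC symbols) before
integration. The input namespace is auto-detected by a regex majority vote
over the supplied identifiers (Ensembl ENSG accessions, numeric Entrez ids,
UniProt accessions, otherwise HGNC symbols). Identifiers that do not resolve
in the bundled cross-reference are kept under a reserved ``unmapped:`` prefix
so the mapping is total and idempotent.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from importlib import resources
from typing import Dict, Iterable, List

import pandas as pd

from .errors import InputError

logger = logging.getLogger(__name__)

UNMAPPED_PREFIX = "unmapped:"

_ENSEMBL_RE = re.compile(r"^ENSG\d{10,}$")
_ENTREZ_RE = re.compile(r"^\d+$")
_UNIPROT_RE = re.compile(r"^[OPQ][0-9][A-Z0-9]{3}[0-9]$|^[A-NR-Z][0-9][A-Z][A-Z0-9]{2}[0-9]$")

NAMESPACES = ("hgnc", "entrez", "ensembl", "uniprot")


@dataclass
class IdentifierMap:
    """Cross-reference table; unified namespace is the HGNC symbol column."""

    table: pd.DataFrame  # columns: hgnc, entrez, ensembl, uniprot

    def __post_init__(self):
        missing = [c for c in NAMESPACES if c not in self.table.columns]
        if missing:
            raise InputError(f"identifier map: missing columns {missing}")
        self._lookup: Dict[str, Dict[str, str]] = {}
        for ns in NAMESPACES:
            lut: Dict[str, str] = {}
            for key, target in zip(self.table[ns].astype(str), self.table["hgnc"].astype(str)):
                if key in lut and lut[key] != target:
                    # many-to-one collision: keep lexicographically smallest target
                    chosen = min(lut[key], target)
                    logger.warning("identifier map: %s %r maps to multiple symbols; keeping %s",
                                   ns, key, chosen)
                    lut[key] = chosen
                else:
                    lut.setdefault(key, target)
            self._lookup[ns] = lut

    def known_symbols(self) -> set:
        return set(self.table["hgnc"].astype(str))


def load_default_map() -> IdentifierMap:
    ref = resources.files("stratomics.data.knowledge") / "id_map.tsv"
    with resources.as_file(ref) as path:
        table = pd.read_csv(path, sep="\t", comment="#")
    return IdentifierMap(table)


def detect_namespace(ids: Iterable[str]) -> str:
    """Majority regex vote; fatal if the minority share exceeds 20%."""
    ids = [str(i) for i in ids]
    if not ids:
        raise InputError("detect_namespace: empty identifier list")
    votes = {ns: 0 for ns in NAMESPACES}
    for i in ids:
        if i.startswith(UNMAPPED_PREFIX):
            votes["hgnc"] += 1  # already-unified fallbacks count as symbols
        elif _ENSEMBL_RE.match(i):
            votes["ensembl"] += 1
        elif _ENTREZ_RE.match(i):
            votes["entrez"] += 1
        elif _UNIPROT_RE.match(i):
            votes["uniprot"] += 1
        else:
            votes["hgnc"] += 1
    winner = max(votes, key=votes.get)
    minority = len(ids) - votes[winner]
    if minority / len(ids) > 0.20:
        raise InputError(
            f"ambiguous namespace: {votes[winner]}/{len(ids)} ids look like {winner}, "
            f"{minority} do not (minority share above 20%)")
    return winner


def map_identifiers(ids: List[str], mapping: IdentifierMap | None = None) -> Dict[str, str]:
    """Map every input id to the unified namespace. Total: unknown ids come
    back under the ``unmapped:`` prefix; already-prefixed ids pass through."""
    if mapping is None:
        mapping = load_default_map()
    ids = [str(i) for i in ids]
    ns = detect_namespace(ids)
    lut = mapping._lookup[ns]
    symbol_lut = mapping._lookup["hgnc"]
    out: Dict[str, str] = {}
    n_unmapped = 0
    for i in ids:
        if i.startswith(UNMAPPED_PREFIX):
            out[i] = i
        elif i in lut:
            out[i] = lut[i]
        elif i in symbol_lut:  # minority ids in the unified namespace still resolve
            out[i] = symbol_lut[i]
        else:
            out[i] = UNMAPPED_PREFIX + i
            n_unmapped += 1
    if n_unmapped:
        logger.warning("identifier mapping: %d/%d ids unmapped (kept with %r prefix)",
                       n_unmapped, len(ids), UNMAPPED_PREFIX)
    return out
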