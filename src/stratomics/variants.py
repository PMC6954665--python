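"""Mutation input: VCF parsing with consequence annotations.

Variants arrive pre-annotated with their predicted protein-level effect,
either inline in a structured INFO field (the common ``CSQ``/``ANN``
pipe-separated dialects) or as a gene-keyed side table. Each alternate allele
becomes one :class:`MutationRecord`; multi-allelic sites are split.
Consequences outside the controlled vocabulary coerce to ``other`` with a
warning, unannotated variants get ``other``/``MODIFIER``.

Coordinate convention: VCF positions stay 1-based at this boundary; interval
arithmetic elsewhere in the package (segment overlap, exon filters) converts
once to 0-based half-open (see :mod:`stratomics.segments`).
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pysam

from .errors import InputError

logger = logging.getLogger(__name__)

CONSEQUENCES = (
    "missense_variant",
    "stop_gained",
    "frameshift_variant",
    "splice_acceptor_variant",
    "splice_donor_variant",
    "synonymous_variant",
    "other",
)
IMPACTS = ("HIGH", "MODERATE", "LOW", "MODIFIER")
ORIGINS = ("somatic", "germline")

# Default impact per consequence when the annotation supplies none.
_CONSEQUENCE_IMPACT = {
    "stop_gained": "HIGH",
    "frameshift_variant": "HIGH",
    "splice_acceptor_variant": "HIGH",
    "splice_donor_variant": "HIGH",
    "missense_variant": "MODERATE",
    "synonymous_variant": "LOW",
    "other": "MODIFIER",
}

_SCORE_RE = re.compile(r"\(?([0-9]*\.?[0-9]+)\)?$")


@dataclass
class MutationRecord:
    chrom: str
    pos: int                      # 1-based, VCF convention
    ref: str
    alt: str
    origin: str
    gene_id: Optional[str] = None
    consequence: str = "other"
    impact: str = "MODIFIER"
    sift: Optional[float] = None
    polyphen: Optional[float] = None

    def __post_init__(self):
        if self.pos < 1:
            raise InputError(f"mutation {self.chrom}:{self.pos}: pos must be >= 1")
        if self.alt == self.ref:
            raise InputError(f"mutation {self.chrom}:{self.pos}: alt equals ref")
        if self.origin not in ORIGINS:
            raise InputError(f"mutation {self.chrom}:{self.pos}: origin {self.origin!r}")
        if self.consequence not in CONSEQUENCES:
            logger.warning("consequence %r outside vocabulary; coerced to 'other'",
                           self.consequence)
            self.consequence = "other"
            self.impact = "MODIFIER"
        if self.impact not in IMPACTS:
            logger.warning("impact %r outside vocabulary; coerced to MODIFIER", self.impact)
            self.impact = "MODIFIER"
        for name in ("sift", "polyphen"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise InputError(f"mutation {self.chrom}:{self.pos}: {name}={v} outside [0,1]")


def _parse_score(raw: str) -> Optional[float]:
    """Accept bare numbers or VeP-style 'deleterious(0.02)'."""
    if not raw:
        return None
    m = _SCORE_RE.search(raw)
    return float(m.group(1)) if m else None


def _csq_field_names(header: pysam.VariantHeader, tag: str) -> Optional[List[str]]:
    rec = header.info.get(tag)
    if rec is None:
        return None
    desc = rec.description or ""
    if "Format:" in desc:
        return [f.strip() for f in desc.split("Format:")[1].strip().strip("'\"").split("|")]
    return None


def _annotation_for_alt(entries: Sequence[str], names: List[str], alt: str) -> Optional[Dict[str, str]]:
    parsed = []
    for entry in entries:
        values = entry.split("|")
        d = dict(zip(names, values))
        parsed.append(d)
    for d in parsed:  # prefer the entry whose Allele matches this alt
        if d.get("Allele", d.get("ALT", "")) == alt:
            return d
    return parsed[0] if parsed else None


def read_vcf(path, origin: str,
             side_table: Optional[Dict[str, Tuple[str, str, Optional[float], Optional[float]]]] = None,
             gene_of_position=None) -> List[MutationRecord]:
    """Parse a VCF 4.x file into one record per alternate allele.

    ``origin`` labels every record somatic or germline. If the file carries a
    VeP-style ``CSQ`` or ``ANN`` INFO field its consequence/impact/SIFT/
    PolyPhen/SYMBOL entries are used; otherwise ``side_table`` (gene_id ->
    (consequence, impact, sift, polyphen)) plus a ``gene_of_position(chrom,
    pos)`` locator may annotate records.
    """
    if origin not in ORIGINS:
        raise InputError(f"read_vcf: origin must be one of {ORIGINS}")
    try:
        vcf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise InputError(f"{path}: cannot open VCF: {exc}") from exc
    csq_tag = next((t for t in ("CSQ", "ANN") if t in vcf.header.info), None)
    csq_names = _csq_field_names(vcf.header, csq_tag) if csq_tag else None

    records: List[MutationRecord] = []
    line_no = len(str(vcf.header).splitlines())
    try:
        for rec in vcf:
            line_no += 1
            if rec.ref is None or not rec.alts:
                raise InputError(f"{path}: malformed VCF line {line_no}: missing REF/ALT")
            entries = rec.info.get(csq_tag) if csq_tag and csq_tag in rec.info else None
            if isinstance(entries, str):
                entries = (entries,)
            for alt in rec.alts:
                gene = consequence = None
                impact = sift = polyphen = None
                if entries and csq_names:
                    ann = _annotation_for_alt(entries, csq_names, alt)
                    if ann:
                        gene = ann.get("SYMBOL") or ann.get("Gene_Name") or None
                        consequence = (ann.get("Consequence") or ann.get("Annotation") or
                                       "").split("&")[0] or None
                        impact = ann.get("IMPACT") or ann.get("Annotation_Impact") or None
                        sift = _parse_score(ann.get("SIFT", ""))
                        polyphen = _parse_score(ann.get("PolyPhen", ""))
                elif side_table is not None and gene_of_position is not None:
                    gene = gene_of_position(rec.chrom, rec.pos)
                    if gene in side_table:
                        consequence, impact, sift, polyphen = side_table[gene]
                records.append(MutationRecord(
                    chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=alt, origin=origin,
                    gene_id=gene,
                    consequence=consequence or "other",
                    impact=impact or _CONSEQUENCE_IMPACT.get(consequence or "other", "MODIFIER"),
                    sift=sift, polyphen=polyphen))
    except (ValueError, OSError) as exc:
        if isinstance(exc, InputError):
            raise
        raise InputError(f"{path}: malformed VCF line {line_no + 1}: {exc}") from exc
    return records


def write_vcf(records: Sequence[MutationRecord], path, contigs: Sequence[str]) -> None:
    """Write records to an uncompressed VCF with a CSQ annotation field."""
    header = pysam.VariantHeader()
    for c in contigs:
        header.contigs.add(c, length=300_000_000)
    header.info.add("CSQ", ".", "String",
                    "Consequence annotations. Format: Allele|Consequence|IMPACT|SYMBOL|SIFT|PolyPhen")
    out = pysam.VariantFile(str(path), "w", header=header)
    for m in sorted(records, key=lambda r: (contigs.index(r.chrom), r.pos, r.alt)):
        rec = out.new_record(contig=m.chrom, start=m.pos - 1, stop=m.pos - 1 + len(m.ref),
                             alleles=(m.ref, m.alt))
        csq = "|".join([
            m.alt, m.consequence, m.impact, m.gene_id or "",
            "" if m.sift is None else f"{m.sift:g}",
            "" if m.polyphen is None else f"{m.polyphen:g}",
        ])
        rec.info["CSQ"] = csq
        out.write(rec)
    out.close()


def group_by_gene(records: Sequence[MutationRecord]) -> Dict[str, List[MutationRecord]]:
    grouped: Dict[str, List[MutationRecord]] = {}
    for m in records:
        if m.gene_id:
            grouped.setdefault(m.gene_id, []).append(m)
    return grouped
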