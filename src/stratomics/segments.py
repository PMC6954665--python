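"""Copy-number segments (SEG format).

SEG files carry per-segment mean log2 ratios of tumor vs. normal copy number,
with 1-based inclusive coordinates. This module is the single place where
coordinates are converted to the package-internal 0-based half-open
convention; downstream interval arithmetic assumes it. Overlapping segments
on one chromosome are resolved to disjoint pieces whose log-ratio is the
per-base mean of the covering segments (logged as a warning).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Sequence

import pandas as pd

from .errors import InputError

logger = logging.getLogger(__name__)


@dataclass
class SegmentRecord:
    chrom: str
    start: int        # 0-based half-open internally
    end: int
    log_ratio: float
    origin: str = "somatic"

    def __post_init__(self):
        if self.start >= self.end:
            raise InputError(f"segment {self.chrom}:{self.start}-{self.end}: empty interval")
        if not pd.notna(self.log_ratio) or self.log_ratio in (float("inf"), float("-inf")):
            raise InputError(f"segment {self.chrom}:{self.start}-{self.end}: non-finite log-ratio")


def resolve_overlaps(segments: Sequence[SegmentRecord]) -> List[SegmentRecord]:
    """Split overlapping segments into disjoint elementary intervals; each
    piece takes the mean log-ratio of all segments covering it."""
    out: List[SegmentRecord] = []
    by_chrom: dict = {}
    for s in segments:
        by_chrom.setdefault((s.chrom, s.origin), []).append(s)
    warned = False
    for (chrom, origin), segs in by_chrom.items():
        points = sorted({p for s in segs for p in (s.start, s.end)})
        covered = False
        for a, b in zip(points[:-1], points[1:]):
            cover = [s.log_ratio for s in segs if s.start < b and s.end > a]
            if not cover:
                continue
            if len(cover) > 1:
                covered = True
            out.append(SegmentRecord(chrom, a, b, sum(cover) / len(cover), origin))
        if covered and not warned:
            logger.warning("overlapping SEG segments on %s resolved by per-base mean", chrom)
            warned = True
    return sorted(out, key=lambda s: (s.chrom, s.start))


def read_seg(path, origin: str = "somatic") -> List[SegmentRecord]:
    """Read a SEG file (sample, chrom, start, end, [num_mark,] seg_mean)."""
    try:
        df = pd.read_csv(path, sep="\t", header=0, comment="#")
    except Exception as exc:
        raise InputError(f"{path}: cannot parse SEG file: {exc}") from exc
    if df.shape[1] < 5:
        raise InputError(f"{path}: SEG needs >=5 columns (sample, chrom, start, end, seg_mean)")
    chrom_col, start_col, end_col = df.columns[1], df.columns[2], df.columns[3]
    mean_col = df.columns[-1]
    segments: List[SegmentRecord] = []
    for i, row in df.iterrows():
        try:
            start = int(row[start_col])
            end = int(row[end_col])
            lr = float(row[mean_col])
        except (TypeError, ValueError) as exc:
            raise InputError(f"{path}: row {i + 2}: non-numeric coordinates or mean") from exc
        if start > end:
            raise InputError(f"{path}: row {i + 2}: start > end")
        # SEG is 1-based inclusive; convert once to 0-based half-open
        segments.append(SegmentRecord(str(row[chrom_col]), start - 1, end, lr, origin))
    return resolve_overlaps(segments)


def write_seg(segments: Sequence[SegmentRecord], path, sample: str = "sample") -> None:
    rows = [{"ID": sample, "chrom": s.chrom, "loc.start": s.start + 1, "loc.end": s.end,
             "num.mark": max(1, (s.end - s.start) // 1000), "seg.mean": s.log_ratio}
            for s in segments]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
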