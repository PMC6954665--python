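"""Expression input and per-gene deregulation scores.

A tumor profile is compared against one or more control profiles (a matched
normal, or other tumors). With a single control the per-gene deregulation
score is a log2 fold-change with a pseudocount stabilizer; with two or more
controls it is a z-score against the control mean and sample (n-1) standard
deviation. Genes whose controls have zero spread get score 0 and are flagged
rather than producing infinities.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .errors import InputError

logger = logging.getLogger(__name__)

LOG_FOLD_CHANGE = "log_fold_change"
Z_SCORE = "z_score"
PRECOMPUTED = "precomputed"


@dataclass
class ExpressionTable:
    """One row per gene: tumor value plus a fixed-length list of controls."""

    genes: List[str]
    tumor: np.ndarray            # shape (n_genes,)
    controls: np.ndarray         # shape (n_genes, n_controls)

    def __post_init__(self):
        self.tumor = np.asarray(self.tumor, dtype=float)
        self.controls = np.atleast_2d(np.asarray(self.controls, dtype=float))
        if self.controls.shape[0] != len(self.genes):
            self.controls = self.controls.reshape(len(self.genes), -1)
        if len(self.genes) != len(self.tumor):
            raise InputError("expression table: gene/tumor length mismatch")
        if not np.all(np.isfinite(self.tumor)) or not np.all(np.isfinite(self.controls)):
            raise InputError("expression table: non-finite values")

    @property
    def n_controls(self) -> int:
        return self.controls.shape[1]


@dataclass
class DeregulationScores:
    """gene_id -> deregulation score, with a uniform score kind."""

    scores: Dict[str, float]
    score_kind: str
    flagged_genes: List[str] = field(default_factory=list)

    def __post_init__(self):
        if self.score_kind not in (LOG_FOLD_CHANGE, Z_SCORE, PRECOMPUTED):
            raise InputError(f"unknown score kind {self.score_kind!r}")
        bad = [g for g, v in self.scores.items() if not np.isfinite(v)]
        if bad:
            raise InputError(f"non-finite deregulation scores for {bad[:5]}")

    def __len__(self):
        return len(self.scores)

    def get(self, gene: str) -> Optional[float]:
        return self.scores.get(gene)


def read_expression(path, gene_column: int = 0, tumor_column: int = 1) -> ExpressionTable:
    """Read a TSV expression table: header row, gene ids, one tumor column,
    remaining columns controls. Duplicate gene rows collapse to their mean
    (logged)."""
    try:
        df = pd.read_csv(path, sep="\t", header=0, comment="#")
    except Exception as exc:
        raise InputError(f"{path}: cannot parse expression table: {exc}") from exc
    if df.shape[1] < 2:
        raise InputError(f"{path}: missing tumor column (need gene id + >=1 value column)")
    gene_col = df.columns[gene_column]
    value_cols = [c for i, c in enumerate(df.columns) if i != gene_column]
    for col in value_cols:
        numeric = pd.to_numeric(df[col], errors="coerce")
        if numeric.isna().any():
            row = int(numeric.index[numeric.isna()][0])
            raise InputError(f"{path}: non-numeric cell at row {row + 2}, column {col!r}")
        df[col] = numeric
    if df[gene_col].duplicated().any():
        dups = df[gene_col][df[gene_col].duplicated()].unique()
        logger.warning("%s: %d duplicated gene rows collapsed by mean (e.g. %s)",
                       path, len(dups), dups[0])
        df = df.groupby(gene_col, sort=False, as_index=False).mean()
    genes = df[gene_col].astype(str).tolist()
    tumor_col = value_cols[tumor_column - 1]
    control_cols = [c for c in value_cols if c != tumor_col]
    return ExpressionTable(
        genes=genes,
        tumor=df[tumor_col].to_numpy(),
        controls=df[control_cols].to_numpy() if control_cols else np.empty((len(genes), 0)),
    )


def write_expression(table: ExpressionTable, path, tumor_name: str = "tumor") -> None:
    cols = {"gene_id": table.genes, tumor_name: table.tumor}
    for j in range(table.n_controls):
        cols[f"control_{j + 1}"] = table.controls[:, j]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def compute_deregulation(expr: ExpressionTable, pseudocount: float = 1.0) -> DeregulationScores:
    """Per-gene deregulation: log2 fold-change (1 control) or z-score (>=2)."""
    if pseudocount <= 0:
        raise InputError("pseudocount must be positive")
    if expr.n_controls == 0:
        raise InputError("compute_deregulation: every gene needs >=1 control value")
    flagged: List[str] = []
    if expr.n_controls == 1:
        ctrl = expr.controls[:, 0]
        scores = np.log2((expr.tumor + pseudocount) / (ctrl + pseudocount))
        kind = LOG_FOLD_CHANGE
    else:
        mean = expr.controls.mean(axis=1)
        sd = expr.controls.std(axis=1, ddof=1)
        zero = sd == 0
        scores = np.zeros(len(expr.genes))
        np.divide(expr.tumor - mean, sd, out=scores, where=~zero)
        if zero.any():
            flagged = [g for g, z in zip(expr.genes, zero) if z]
            logger.warning("z-score: %d genes with zero control spread set to 0", len(flagged))
        kind = Z_SCORE
    return DeregulationScores(dict(zip(expr.genes, scores.tolist())), kind, flagged)


def precomputed_scores(mapping: Dict[str, float]) -> DeregulationScores:
    """Wrap externally computed differential-expression scores."""
    return DeregulationScores(dict(mapping), PRECOMPUTED)
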