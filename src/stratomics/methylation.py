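"""Promoter methylation input and differential methylation scores.

A whitespace-separated table carries per-gene beta values (tumor plus
controls) or precomputed differential scores. Differential methylation uses
the same machinery as expression: log-fold-quotient against a single control
(with a small pseudocount suited to [0,1] betas) or a z-score against two or
more controls.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List

import numpy as np
import pandas as pd

from .errors import InputError
from .expression import ExpressionTable, DeregulationScores, compute_deregulation, PRECOMPUTED


@dataclass
class MethylationTable:
    genes: List[str]
    tumor_betas: np.ndarray
    control_betas: np.ndarray      # shape (n_genes, n_controls); may be empty

    def __post_init__(self):
        self.tumor_betas = np.asarray(self.tumor_betas, dtype=float)
        self.control_betas = np.asarray(self.control_betas, dtype=float).reshape(len(self.genes), -1)
        for name, arr in (("tumor", self.tumor_betas), ("control", self.control_betas)):
            if arr.size and ((arr < 0) | (arr > 1)).any():
                bad = float(arr[(arr < 0) | (arr > 1)].flat[0])
                raise InputError(f"methylation: {name} beta {bad} outside [0, 1]")


def read_methylation(path) -> MethylationTable | DeregulationScores:
    """Read a whitespace-separated methylation table.

    Two layouts: gene + >=2 value columns (tumor betas + controls) returns a
    :class:`MethylationTable`; gene + 1 column is interpreted as precomputed
    differential scores.
    """
    try:
        df = pd.read_csv(path, sep=r"\s+", header=0, comment="#")
    except Exception as exc:
        raise InputError(f"{path}: cannot parse methylation table: {exc}") from exc
    if df.shape[1] < 2:
        raise InputError(f"{path}: methylation table needs a gene column plus values")
    for col in df.columns[1:]:
        numeric = pd.to_numeric(df[col], errors="coerce")
        if numeric.isna().any():
            row = int(numeric.index[numeric.isna()][0])
            raise InputError(f"{path}: non-numeric cell at row {row + 2}, column {col!r}")
        df[col] = numeric
    genes = df.iloc[:, 0].astype(str).tolist()
    if df.shape[1] == 2:
        return DeregulationScores(dict(zip(genes, df.iloc[:, 1].tolist())), PRECOMPUTED)
    return MethylationTable(genes, df.iloc[:, 1].to_numpy(), df.iloc[:, 2:].to_numpy())


def compute_methylation_diff(table: MethylationTable, pseudocount: float = 0.01) -> DeregulationScores:
    """Differential methylation scores (log-fold-quotient or z-score)."""
    if table.control_betas.shape[1] == 0:
        raise InputError("differential methylation requires >=1 control sample")
    expr = ExpressionTable(table.genes, table.tumor_betas, table.control_betas)
    return compute_deregulation(expr, pseudocount=pseudocount)


def write_methylation(table: MethylationTable, path) -> None:
    cols = {"gene_id": table.genes, "tumor": table.tumor_betas}
    for j in range(table.control_betas.shape[1]):
        cols[f"control_{j + 1}"] = table.control_betas[:, j]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)
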