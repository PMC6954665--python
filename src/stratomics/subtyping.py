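"""Intrinsic-subtype assessment against a labeled reference cohort.

The query expression profile is embedded together with the cohort by PCA and
t-SNE on a variance-filtered, cohort-standardized gene panel. Because the
published subtype call is visual, the package adds an explicit k-nearest-
neighbor caller (default k=15) in the standardized full-panel space so the
call is testable; vote fractions are reported alongside the majority label.

The reference frame is always the cohort's: genes are standardized by cohort
mean and standard deviation so the query cannot shift it.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

from .errors import InputError

SUBTYPES = ("luminal A", "luminal B", "HER2-enriched", "basal-like")
DEFAULT_TOP_GENES = 2000
DEFAULT_K = 15


@dataclass
class ReferenceCohort:
    genes: List[str]
    expression: np.ndarray            # samples x genes
    sample_ids: List[str]
    labels: Dict[str, str]
    activity_matrix: Optional[pd.DataFrame] = None   # samples x pathways
    tmb_values: Optional[Dict[str, float]] = None

    def __post_init__(self):
        self.expression = np.asarray(self.expression, dtype=float)
        if self.expression.shape != (len(self.sample_ids), len(self.genes)):
            raise InputError("reference cohort: expression shape mismatch")
        unlabeled = [s for s in self.sample_ids if s not in self.labels]
        if unlabeled:
            raise InputError(f"reference cohort: unlabeled samples {unlabeled[:5]}")

    @classmethod
    def from_files(cls, expression_tsv, labels_tsv, activity_tsv=None) -> "ReferenceCohort":
        expr = pd.read_csv(expression_tsv, sep="\t", index_col=0)
        labels = pd.read_csv(labels_tsv, sep="\t", index_col=0).iloc[:, 0].to_dict()
        activity = pd.read_csv(activity_tsv, sep="\t", index_col=0) if activity_tsv else None
        return cls(genes=list(expr.columns), expression=expr.to_numpy(),
                   sample_ids=list(expr.index.astype(str)), labels=labels,
                   activity_matrix=activity)

    def to_files(self, expression_tsv, labels_tsv) -> None:
        pd.DataFrame(self.expression, index=self.sample_ids, columns=self.genes)\
            .to_csv(expression_tsv, sep="\t")
        pd.DataFrame({"subtype": [self.labels[s] for s in self.sample_ids]},
                     index=self.sample_ids).to_csv(labels_tsv, sep="\t")


@dataclass
class Embedding:
    method: str
    coordinates: Dict[str, Tuple[float, float]]
    labels: Dict[str, str]
    query_id: str

    def to_json(self, path=None) -> dict:
        data = {"method": self.method, "query_id": self.query_id,
                "samples": [{"sample_id": s, "x": x, "y": y,
                             "subtype": self.labels.get(s),
                             "is_query": s == self.query_id}
                            for s, (x, y) in self.coordinates.items()]}
        if path is not None:
            with open(path, "w") as fh:
                json.dump(data, fh, indent=1)
        return data


def _standardized_panel(query: Dict[str, float], cohort: ReferenceCohort,
                        top_genes: int = DEFAULT_TOP_GENES
                        ) -> Tuple[np.ndarray, np.ndarray, List[str]]:
    """Project query and cohort onto the shared gene panel, standardized by
    cohort statistics; returns (cohort_matrix, query_vector, panel)."""
    shared = [g for g in cohort.genes if g in query]
    if len(shared) < 0.5 * len(cohort.genes):
        raise InputError(
            f"query covers only {len(shared)}/{len(cohort.genes)} cohort panel genes "
            "(<50% overlap)")
    idx = [cohort.genes.index(g) for g in shared]
    X = cohort.expression[:, idx]
    sd = X.std(axis=0, ddof=0)
    keep = sd > 0
    X, sd = X[:, keep], sd[keep]
    shared = [g for g, k in zip(shared, keep) if k]
    if top_genes and X.shape[1] > top_genes:
        var_order = np.argsort(X.var(axis=0))[::-1][:top_genes]
        var_order.sort()
        X, sd = X[:, var_order], sd[var_order]
        shared = [shared[i] for i in var_order]
    mean = X.mean(axis=0)
    q = (np.array([query[g] for g in shared]) - mean) / sd
    return (X - mean) / sd, q, shared


def embed(query: Dict[str, float], cohort: ReferenceCohort, method: str = "pca",
          seed: int = 0, query_id: str = "query",
          top_genes: int = DEFAULT_TOP_GENES) -> Embedding:
    """2-D embedding of cohort plus query by PCA or t-SNE."""
    X, q, _ = _standardized_panel(query, cohort, top_genes)
    stacked = np.vstack([X, q])
    if method == "pca":
        pca = PCA(n_components=2, random_state=seed)
        pca.fit(X)  # the query must not shift the reference frame
        # sign convention: largest-|loading| entry of each component positive
        for comp in range(2):
            j = np.argmax(np.abs(pca.components_[comp]))
            if pca.components_[comp, j] < 0:
                pca.components_[comp] *= -1
        coords = pca.transform(stacked)
    elif method == "tsne":
        n = stacked.shape[0]
        perplexity = min(30.0, max(2.0, (n - 1) / 3))
        coords = TSNE(n_components=2, perplexity=perplexity, random_state=seed,
                      init="pca").fit_transform(stacked)
    else:
        raise InputError(f"embed: unknown method {method!r}")
    ids = list(cohort.sample_ids) + [query_id]
    return Embedding(method,
                     {s: (float(x), float(y)) for s, (x, y) in zip(ids, coords)},
                     dict(cohort.labels), query_id)


def call_subtype(query: Dict[str, float], cohort: ReferenceCohort, k: int = DEFAULT_K,
                 top_genes: int = DEFAULT_TOP_GENES) -> Tuple[str, Dict[str, float]]:
    """Majority subtype among the k nearest cohort samples (standardized
    full-panel Euclidean distance); ties break toward smaller mean distance."""
    X, q, _ = _standardized_panel(query, cohort, top_genes)
    dist = np.sqrt(((X - q) ** 2).sum(axis=1))
    k = min(k, len(dist))
    nearest = np.argsort(dist, kind="stable")[:k]
    votes: Dict[str, int] = {}
    dists: Dict[str, List[float]] = {}
    for i in nearest:
        lab = cohort.labels[cohort.sample_ids[i]]
        votes[lab] = votes.get(lab, 0) + 1
        dists.setdefault(lab, []).append(float(dist[i]))
    fractions = {lab: n / k for lab, n in votes.items()}
    best = max(votes.values())
    tied = [lab for lab, n in votes.items() if n == best]
    winner = min(tied, key=lambda lab: np.mean(dists[lab])) if len(tied) > 1 else tied[0]
    return winner, fractions
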