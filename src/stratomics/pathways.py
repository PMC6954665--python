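"""Pathway activity scores with a permutation null.

The raw activity of a pathway is the weighted sum of the deregulation scores
of its member genes (inhibitor members enter with negative sign). Because the
raw sum has no natural scale, it is normalized to [0, 1] as its midrank
position within a permutation null: the gene->score assignment is permuted
over *all* scored genes and the sum recomputed ``n_perm`` times. The same
null yields a two-sided empirical P-value with add-one correction,

    p = (1 + #{ |null| >= |observed| }) / (n_perm + 1),

so a pathway can be significantly active or significantly *inactive*.
P-values across the 20 pathways are Benjamini-Hochberg adjusted. Activities
map onto qualitative labels: 'medium' on the closed interval [0.4, 0.6],
'high' on (0.6, 1], 'low' on the complement [0, 0.4).

Pathways with fewer than ``min_fraction_scored`` (default 25%) of members
scored are reported as not assessable and excluded from labels and exports.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from statsmodels.stats.multitest import multipletests

from .errors import InputError
from .expression import DeregulationScores
from .knowledge import KnowledgeBundle, PathwayDefinition

DEFAULT_N_PERM = 1000
DEFAULT_SEED = 42
MIN_FRACTION_SCORED = 0.25

LABEL_LOW, LABEL_MEDIUM, LABEL_HIGH = "low", "medium", "high"


@dataclass
class PathwayActivityResult:
    pathway_id: str
    raw_score: Optional[float]
    activity: Optional[float]
    p_value: Optional[float]
    p_adjusted: Optional[float] = None
    label: Optional[str] = None
    n_genes_used: int = 0
    n_permutations: int = 0
    assessable: bool = True

    def to_dict(self) -> dict:
        return {
            "pathway_id": self.pathway_id, "raw_score": self.raw_score,
            "activity": self.activity, "p_value": self.p_value,
            "p_adjusted": self.p_adjusted, "label": self.label,
            "n_genes_used": self.n_genes_used, "n_permutations": self.n_permutations,
            "assessable": self.assessable,
        }


@dataclass
class ActivityVector:
    sample_id: str
    pathway_ids: List[str]
    activities: np.ndarray  # NaN where not assessable

    def __post_init__(self):
        self.activities = np.asarray(self.activities, dtype=float)
        if len(self.pathway_ids) != len(self.activities):
            raise InputError("activity vector: pathway/activity length mismatch")


def pathway_raw_score(dereg: DeregulationScores, pw: PathwayDefinition) -> Tuple[Optional[float], int]:
    """Weighted sum of deregulation scores over scored members.

    Returns (score, n_genes_used); score is None when no member is scored.
    """
    weights = pw.signed_weights()
    present = [(g, w) for g, w in weights.items() if dereg.get(g) is not None]
    if not present:
        return None, 0
    return float(sum(w * dereg.scores[g] for g, w in present)), len(present)


def _null_scores(dereg: DeregulationScores, pw: PathwayDefinition,
                 n_perm: int, rng: np.random.Generator) -> np.ndarray:
    """Permutation null: redraw the member scores from the pool of all scored
    genes, without replacement, keeping the member weights fixed."""
    weights = pw.signed_weights()
    present_w = np.array([w for g, w in weights.items() if dereg.get(g) is not None])
    pool = np.fromiter(dereg.scores.values(), dtype=float)
    order = np.argsort(rng.random((n_perm, pool.size)), axis=1)[:, :len(present_w)]
    return pool[order] @ present_w


def midrank_position(value: float, reference: np.ndarray) -> float:
    """Midrank of ``value`` within ``reference`` divided by (len+1), in (0,1)."""
    reference = np.asarray(reference, dtype=float)
    below = int(np.sum(reference < value))
    ties = int(np.sum(reference == value))
    return (below + (ties + 1) / 2.0) / (len(reference) + 1)


def normalize_activity(raw_score: float, null_scores: Sequence[float]) -> float:
    """Empirical-CDF position of the raw score within its permutation null."""
    null_scores = np.asarray(null_scores, dtype=float)
    if null_scores.size == 0:
        raise InputError("normalize_activity: empty null")
    return midrank_position(raw_score, null_scores)


def empirical_pvalue(raw_score: float, dereg: DeregulationScores, pw: PathwayDefinition,
                     n_perm: int = DEFAULT_N_PERM, seed: int = DEFAULT_SEED,
                     method: str = "sample") -> Tuple[float, np.ndarray]:
    """Two-sided add-one permutation P-value plus the null scores.

    ``method='sample'`` draws ``n_perm`` random gene->score reassignments;
    ``method='exhaustive'`` enumerates every ordered assignment of pool
    scores to the scored members (only feasible for tiny universes) and
    replaces the add-one numerator convention accordingly.
    """
    if method == "exhaustive":
        from itertools import permutations as _perms
        from math import perm as _nperm
        weights = pw.signed_weights()
        w = np.array([wt for g, wt in weights.items() if dereg.get(g) is not None])
        pool = np.fromiter(dereg.scores.values(), dtype=float)
        if _nperm(pool.size, w.size) > 200_000:
            raise InputError("exhaustive enumeration infeasible for this universe size")
        null = np.array([w @ np.array(t) for t in _perms(pool, w.size)])
        p = (1 + int(np.sum(np.abs(null) >= abs(raw_score)))) / (null.size + 1)
        return p, null
    if method != "sample":
        raise InputError(f"empirical_pvalue: unknown method {method!r}")
    if n_perm < 100:
        raise InputError("empirical_pvalue: n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    null = _null_scores(dereg, pw, n_perm, rng)
    p = (1 + int(np.sum(np.abs(null) >= abs(raw_score)))) / (n_perm + 1)
    return p, null


def adjust_bh(p_values: Sequence[float]) -> List[float]:
    """Benjamini-Hochberg step-up adjusted P-values, clipped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1)):
        raise InputError("adjust_bh: p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1].tolist()


def label_activity(activity: float) -> str:
    """Qualitative label: medium on [0.4, 0.6], high on (0.6, 1], else low."""
    if not (0.0 <= activity <= 1.0):
        raise InputError(f"label_activity: activity {activity} outside [0, 1]")
    if 0.4 <= activity <= 0.6:
        return LABEL_MEDIUM
    if activity > 0.6:
        return LABEL_HIGH
    return LABEL_LOW


def score_pathways(dereg: DeregulationScores, kb: KnowledgeBundle,
                   n_perm: int = DEFAULT_N_PERM, seed: int = DEFAULT_SEED,
                   min_fraction_scored: float = MIN_FRACTION_SCORED
                   ) -> List[PathwayActivityResult]:
    """Activity, empirical P and BH-adjusted P for every pathway in the bundle."""
    if n_perm < 100:
        raise InputError("score_pathways: n_perm must be >= 100")
    pool = np.fromiter(dereg.scores.values(), dtype=float)
    kmax = max(len(pw.members) for pw in kb.pathways)
    rng = np.random.default_rng(seed)
    # one permutation of the score pool per null draw, shared across pathways
    order = np.argsort(rng.random((n_perm, pool.size)), axis=1)[:, :kmax]
    perm_scores = pool[order]
    results: List[PathwayActivityResult] = []
    for pw in kb.pathways:
        raw, n_used = pathway_raw_score(dereg, pw)
        if raw is None or n_used / len(pw.members) < min_fraction_scored:
            results.append(PathwayActivityResult(pw.pathway_id, raw, None, None,
                                                 n_genes_used=n_used, assessable=False))
            continue
        weights = pw.signed_weights()
        w = np.array([wt for g, wt in weights.items() if dereg.get(g) is not None])
        null = perm_scores[:, :len(w)] @ w
        p = (1 + int(np.sum(np.abs(null) >= abs(raw)))) / (n_perm + 1)
        act = normalize_activity(raw, null)
        results.append(PathwayActivityResult(pw.pathway_id, raw, act, p,
                                             label=label_activity(act),
                                             n_genes_used=n_used, n_permutations=n_perm))
    assessable = [r for r in results if r.assessable]
    if assessable:
        adjusted = adjust_bh([r.p_value for r in assessable])
        for r, padj in zip(assessable, adjusted):
            r.p_adjusted = padj
    return results


def activity_vector(sample_id: str, results: Sequence[PathwayActivityResult]) -> ActivityVector:
    return ActivityVector(sample_id, [r.pathway_id for r in results],
                          np.array([r.activity if r.assessable else np.nan for r in results]))


def rank_similar_samples(query: ActivityVector, cohort: Sequence[ActivityVector]
                         ) -> List[Tuple[str, float]]:
    """Reference samples sorted by ascending mean-squared activity distance.

    Pathways not assessable in the query are dropped pairwise; ties break by
    sample id.
    """
    ranked = []
    for ref in cohort:
        if ref.pathway_ids != query.pathway_ids:
            raise InputError("rank_similar_samples: pathway order mismatch")
        mask = ~(np.isnan(query.activities) | np.isnan(ref.activities))
        if not mask.any():
            raise InputError("rank_similar_samples: no shared assessable pathways")
        d = float(np.mean((query.activities[mask] - ref.activities[mask]) ** 2))
        ranked.append((ref.sample_id, d))
    return sorted(ranked, key=lambda t: (t[1], t[0]))


def export_radar(results: Sequence[PathwayActivityResult],
                 references: Optional[Dict[str, ActivityVector]] = None,
                 path=None) -> dict:
    """Radar-chart data export: fixed pathway order, activities, adjusted P."""
    data = {
        "pathway_order": [r.pathway_id for r in results],
        "activity": [r.activity for r in results],
        "p_adjusted": [r.p_adjusted for r in results],
        "label": [r.label for r in results],
        "references": {
            sid: [None if np.isnan(a) else float(a) for a in vec.activities]
            for sid, vec in (references or {}).items()
        },
    }
    if path is not None:
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1)
    return data
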