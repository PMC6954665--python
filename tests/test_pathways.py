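"""Pathway activity scoring, permutation nulls, BH adjustment, similarity."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_
from scipy import stats

from stratomics import (InputError, adjust_bh, empirical_pvalue, label_activity,
                        normalize_activity, pathway_raw_score, rank_similar_samples)
from stratomics.expression import DeregulationScores
from stratomics.knowledge import PathwayDefinition
from stratomics.pathways import ActivityVector, activity_vector, score_pathways


def _dereg(mapping):
    return DeregulationScores(dict(mapping), "z_score")


def _pathway(members):
    return PathwayDefinition("PW", "test pathway", members)


def bh_oracle(pvals):
    """Independent textbook step-up implementation."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adjusted = [None] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, pvals[i] * m / rank_from_top)
        adjusted[i] = val
        prev = val
    return adjusted


class TestRawScore:
    def test_activator_sum(self):
        pw = _pathway([("a", 1, "activator"), ("b", 1, "activator"), ("c", 1, "activator")])
        score, n = pathway_raw_score(_dereg({"a": 1, "b": 2, "c": 3}), pw)
        assert score == pytest.approx(6.0)
        assert n == 3

    def test_inhibitor_cancellation(self):
        pw = _pathway([("a", 1, "activator"), ("b", 1, "activator"), ("c", 1, "inhibitor")])
        score, _ = pathway_raw_score(_dereg({"a": 2, "b": 2, "c": 4}), pw)
        assert score == pytest.approx(0.0)

    def test_matches_dot_product_oracle(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(10)]
        weights = rng.uniform(0.5, 2.0, 10)
        roles = ["activator" if i % 3 else "inhibitor" for i in range(10)]
        scores = dict(zip(genes, rng.normal(0, 1, 10)))
        pw = _pathway(list(zip(genes, weights, roles)))
        raw, _ = pathway_raw_score(_dereg(scores), pw)
        oracle = sum((w if r == "activator" else -w) * scores[g]
                     for g, w, r in zip(genes, weights, roles))
        assert raw == pytest.approx(oracle)

    def test_no_members_scored(self):
        pw = _pathway([("x", 1, "activator"), ("y", 1, "activator"), ("z", 1, "activator")])
        score, n = pathway_raw_score(_dereg({"a": 1.0}), pw)
        assert score is None and n == 0


class TestNormalizeActivity:
    def test_above_all_nulls(self):
        null = np.arange(999, dtype=float)
        # midrank 999.5 over 1000 draws
        assert normalize_activity(1e6, null) == pytest.approx(0.9995)

    def test_at_null_median(self):
        null = np.arange(999, dtype=float)
        assert normalize_activity(499.0, null) == pytest.approx(0.5)

    def test_all_zero_scores_yield_half(self):
        null = np.zeros(999)
        assert normalize_activity(0.0, null) == pytest.approx(0.5)

    def test_symmetric_null_centers_on_half(self):
        # degenerate pathway over a sign-symmetric score distribution
        rng = np.random.default_rng(9)
        acts = []
        for _ in range(200):
            null = rng.normal(0, 1, 499)
            acts.append(normalize_activity(rng.normal(0, 1), null))
        assert np.mean(acts) == pytest.approx(0.5, abs=0.02)


class TestEmpiricalPvalue:
    def test_add_one_floor(self):
        genes = {f"g{i}": 0.01 * i for i in range(50)}
        genes["hit"] = 100.0
        pw = _pathway([("hit", 1, "activator"), ("g1", 1, "activator"), ("g2", 1, "activator")])
        p, null = empirical_pvalue(100.0 + genes["g1"] + genes["g2"], _dereg(genes), pw,
                                   n_perm=999, seed=0)
        # observed uses the single huge score thrice less often than any null
        assert p >= 1 / 1000

    def test_whole_universe_pathway_p_one(self):
        genes = {f"g{i}": float(i) for i in range(6)}
        pw = _pathway([(g, 1, "activator") for g in genes])
        raw, _ = pathway_raw_score(_dereg(genes), pw)
        p, _ = empirical_pvalue(raw, _dereg(genes), pw, n_perm=200, seed=1)
        assert p == pytest.approx(1.0)

    def test_exhaustive_matches_enumeration_oracle(self):
        from itertools import permutations
        genes = {"a": 1.3, "b": -0.2, "c": 2.1, "d": 0.4, "e": -1.7}
        members = [("a", 1.0, "activator"), ("b", 0.5, "activator"),
                   ("c", 1.0, "inhibitor"), ("d", 2.0, "activator")]
        pw = _pathway(members)
        dereg = _dereg(genes)
        raw, _ = pathway_raw_score(dereg, pw)
        p, null = empirical_pvalue(raw, dereg, pw, method="exhaustive")
        w = [1.0, 0.5, -1.0, 2.0]
        oracle_null = [sum(wi * si for wi, si in zip(w, perm))
                       for perm in permutations(genes.values(), 4)]
        assert sorted(null.tolist()) == pytest.approx(sorted(oracle_null))
        oracle_p = (1 + sum(abs(s) >= abs(raw) for s in oracle_null)) / (len(oracle_null) + 1)
        assert p == pytest.approx(oracle_p)

    def test_small_n_perm_rejected(self):
        pw = _pathway([("a", 1, "activator")] * 3)
        with pytest.raises(InputError):
            empirical_pvalue(1.0, _dereg({"a": 1.0}), pw, n_perm=10)


class TestAdjustBH:
    def test_hand_computed_example(self):
        assert adjust_bh([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_single_p_unchanged(self):
        assert adjust_bh([0.37]) == pytest.approx([0.37])

    def test_matches_textbook_oracle_elementwise(self):
        rng = np.random.default_rng(21)
        p = rng.uniform(0.001, 1.0, 50).tolist()
        assert adjust_bh(p) == pytest.approx(bh_oracle(p))

    def test_never_decreases_never_exceeds_one(self):
        rng = np.random.default_rng(22)
        for _ in range(20):
            p = rng.uniform(1e-6, 1.0, int(rng.integers(1, 30))).tolist()
            adj = adjust_bh(p)
            assert all(a >= o for a, o in zip(adj, p))
            assert all(a <= 1.0 for a in adj)

    def test_rejects_out_of_range(self):
        with pytest.raises(InputError):
            adjust_bh([0.0, 0.5])


class TestRankFormulaProperties:
    @given(st_.lists(st_.floats(-50, 50), min_size=1, max_size=80),
           st_.floats(-60, 60))
    @settings(deadline=None, derandomize=True, max_examples=100)
    def test_midrank_position_bounded_and_monotone(self, reference, value):
        from stratomics.pathways import midrank_position
        ref = np.asarray(reference)
        pos = midrank_position(value, ref)
        assert 0.0 < pos < 1.0
        assert midrank_position(value + 1.0, ref) >= pos

    @given(st_.lists(st_.floats(1e-6, 1.0), min_size=1, max_size=40))
    @settings(deadline=None, derandomize=True, max_examples=100)
    def test_bh_matches_oracle_on_arbitrary_inputs(self, pvals):
        assert adjust_bh(pvals) == pytest.approx(bh_oracle(pvals))


class TestLabelActivity:
    @pytest.mark.parametrize("activity,label", [
        (0.4, "medium"), (0.6, "medium"), (0.5, "medium"),
        (0.61, "high"), (1.0, "high"),
        (0.0, "low"), (0.39, "low"),
    ])
    def test_interval_boundaries(self, activity, label):
        assert label_activity(activity) == label

    def test_out_of_range_fatal(self):
        with pytest.raises(InputError):
            label_activity(1.2)


class TestSimilarityRanking:
    def test_identical_vector_ranks_first_with_zero_distance(self):
        ids = [f"PW{i}" for i in range(20)]
        q = ActivityVector("q", ids, np.linspace(0, 1, 20))
        refs = [ActivityVector("same", ids, np.linspace(0, 1, 20)),
                ActivityVector("far", ids, np.ones(20))]
        ranked = rank_similar_samples(q, refs)
        assert ranked[0] == ("same", pytest.approx(0.0))

    def test_unit_distance(self):
        ids = [f"PW{i}" for i in range(20)]
        q = ActivityVector("q", ids, np.zeros(20))
        ranked = rank_similar_samples(q, [ActivityVector("r", ids, np.ones(20))])
        assert ranked[0][1] == pytest.approx(1.0)

    def test_ordering_matches_recomputed_oracle(self):
        rng = np.random.default_rng(13)
        ids = [f"PW{i}" for i in range(20)]
        q = ActivityVector("q", ids, rng.uniform(0, 1, 20))
        refs = [ActivityVector(f"s{i:02d}", ids, rng.uniform(0, 1, 20)) for i in range(30)]
        ranked = rank_similar_samples(q, refs)
        oracle = sorted(((r.sample_id, float(np.mean((q.activities - r.activities) ** 2)))
                         for r in refs), key=lambda t: (t[1], t[0]))
        assert [s for s, _ in ranked] == [s for s, _ in oracle]

    def test_nan_pathways_dropped_pairwise(self):
        ids = ["A", "B", "C"]
        q = ActivityVector("q", ids, np.array([0.5, np.nan, 0.5]))
        ranked = rank_similar_samples(q, [ActivityVector("r", ids, np.array([0.5, 1.0, 0.7]))])
        assert ranked[0][1] == pytest.approx(0.02)


class TestScorePathways:
    def test_doubling_scores_leaves_activity_and_p_unchanged(self, kb):
        rng = np.random.default_rng(42)
        genes = {f"SYN{i}": float(s) for i, s in enumerate(rng.normal(0, 1, 800))}
        # seed knowledge genes too so pathways are assessable
        for m in kb.gene_models:
            genes[m.gene_id] = float(rng.normal(0, 1))
        dereg = DeregulationScores(genes, "z_score")
        results = score_pathways(dereg, kb, n_perm=300, seed=5)
        assert all(r.assessable for r in results)
        doubled = DeregulationScores({g: 2 * v for g, v in genes.items()}, "z_score")
        results2 = score_pathways(doubled, kb, n_perm=300, seed=5)
        for a, b in zip(results, results2):
            assert a.activity == pytest.approx(b.activity)
            assert a.p_value == pytest.approx(b.p_value)
            assert b.p_adjusted >= b.p_value

    def test_not_assessable_below_member_fraction(self, kb):
        dereg = DeregulationScores({"KRAS": 1.0}, "z_score")
        results = score_pathways(dereg, kb, n_perm=100, seed=0, min_fraction_scored=0.25)
        mapk = next(r for r in results if r.pathway_id == "MAPK_SIGNALING")
        assert not mapk.assessable and mapk.label is None

    def test_activity_vector_preserves_order(self, kb):
        rng = np.random.default_rng(1)
        genes = {m.gene_id: float(rng.normal()) for m in kb.gene_models}
        results = score_pathways(DeregulationScores(genes, "z_score"), kb,
                                 n_perm=100, seed=2)
        vec = activity_vector("s", results)
        assert vec.pathway_ids == [p.pathway_id for p in kb.pathways]
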