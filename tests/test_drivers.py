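"""Mutation grading, CNA gene mapping and driver prioritization."""
import numpy as np
import pytest

from stratomics import grade_mutation, map_segments_to_genes, prioritize_drivers
from stratomics.bundle import OmicsBundle
from stratomics.clinical import ClinicalRecord
from stratomics.drivers import SEVERITY_POINTS, best_grade
from stratomics.expression import DeregulationScores
from stratomics.knowledge import DriverCatalogEntry, GeneModel
from stratomics.segments import SegmentRecord
from stratomics.variants import MutationRecord


def _mut(gene="TP53", consequence="missense_variant", impact="MODERATE",
         sift=None, polyphen=None, origin="somatic"):
    return MutationRecord("chr1", 100, "A", "T", origin, gene_id=gene,
                          consequence=consequence, impact=impact,
                          sift=sift, polyphen=polyphen)


class TestGradeMutation:
    @pytest.mark.parametrize("kwargs,grade", [
        (dict(consequence="frameshift_variant", impact="HIGH"), "severe"),
        (dict(consequence="stop_gained", impact="HIGH"), "severe"),
        (dict(sift=0.02, polyphen=0.1), "damaging"),
        (dict(sift=0.5, polyphen=0.9), "damaging"),
        (dict(sift=0.5, polyphen=0.5), "moderate"),
        (dict(), "moderate"),
        (dict(consequence="synonymous_variant", impact="LOW"), "low"),
        (dict(consequence="other", impact="MODIFIER"), "unknown"),
    ])
    def test_grading_rules(self, kwargs, grade):
        assert grade_mutation(_mut(**kwargs)) == grade

    def test_high_impact_never_downgraded_by_benign_scores(self):
        # monotonicity: a HIGH-impact consequence dominates score evidence
        m = _mut(consequence="stop_gained", impact="HIGH", sift=1.0, polyphen=0.0)
        assert grade_mutation(m) == "severe"

    def test_best_grade_takes_most_severe(self):
        muts = [_mut(sift=0.5, polyphen=0.5), _mut(consequence="stop_gained", impact="HIGH")]
        assert best_grade(muts) == "severe"
        assert best_grade([]) == "unknown"


class TestMapSegmentsToGenes:
    def test_gene_inside_single_segment(self):
        segs = [SegmentRecord("chr1", 0, 10_000, 1.2)]
        models = [GeneModel("G1", "chr1", 2_000, 3_000)]
        (call,) = map_segments_to_genes(segs, models)
        assert call.call == "amplified"
        assert call.log_ratio == pytest.approx(1.2)

    def test_gene_split_half_and_half(self):
        segs = [SegmentRecord("chr1", 0, 1_000, 1.0), SegmentRecord("chr1", 1_000, 2_000, 0.0)]
        models = [GeneModel("G1", "chr1", 500, 1_500)]
        (call,) = map_segments_to_genes(segs, models)
        assert call.log_ratio == pytest.approx(0.5)
        assert call.call == "amplified"  # default threshold 0.3

    def test_uncovered_gene_omitted_and_deletion_called(self):
        segs = [SegmentRecord("chr1", 0, 1_000, -0.8)]
        models = [GeneModel("G1", "chr1", 100, 200), GeneModel("G2", "chr2", 100, 200)]
        calls = map_segments_to_genes(segs, models)
        assert [c.gene_id for c in calls] == ["G1"]
        assert calls[0].call == "deleted"

    def test_matches_per_base_oracle(self):
        rng = np.random.default_rng(17)
        length = 5_000
        segs, cursor = [], 0
        while cursor < length:
            w = int(rng.integers(100, 800))
            segs.append(SegmentRecord("chr1", cursor, min(cursor + w, length),
                                      float(rng.normal(0, 0.6))))
            cursor += w
        models = []
        for i in range(100):
            a = int(rng.integers(0, length - 50))
            models.append(GeneModel(f"G{i:03d}", "chr1", a, a + int(rng.integers(20, 400))))
        calls = {c.gene_id: c.log_ratio for c in map_segments_to_genes(segs, models)}
        # per-base accumulation oracle
        base = np.full(length + 1000, np.nan)
        for s in segs:
            base[s.start:s.end] = s.log_ratio
        for m in models:
            window = base[m.start:m.end]
            covered = window[~np.isnan(window)]
            if covered.size == 0:
                assert m.gene_id not in calls
            else:
                assert calls[m.gene_id] == pytest.approx(covered.mean())

    def test_weighted_mean_within_overlap_range(self):
        segs = [SegmentRecord("chr1", 0, 500, -1.0), SegmentRecord("chr1", 500, 1_000, 2.0)]
        models = [GeneModel("G1", "chr1", 100, 900)]
        (call,) = map_segments_to_genes(segs, models)
        assert -1.0 <= call.log_ratio <= 2.0


def _bundle(mutations=None, dereg=None, methylation=None):
    return OmicsBundle(
        clinical=ClinicalRecord("P"),
        deregulation=DeregulationScores(dereg or {"TP53": 0.0}, "z_score"),
        mutations=mutations or {},
        methylation_diff=methylation or {})


CATALOG = [DriverCatalogEntry("TP53", "tumor_suppressor", 1.0, "t"),
           DriverCatalogEntry("BRCA1", "tumor_suppressor", 1.0, "t"),
           DriverCatalogEntry("ERBB2", "oncogene", 0.8, "t")]


class TestPrioritizeDrivers:
    def test_severe_tp53_scores_three_and_is_listed(self):
        bundle = _bundle({"TP53": [_mut(consequence="stop_gained", impact="HIGH")]})
        events = prioritize_drivers(bundle, CATALOG)
        assert events[0].gene_id == "TP53"
        assert events[0].priority_score == pytest.approx(3.0)
        assert events[0].severity_grade == "severe"

    def test_unaltered_catalog_gene_absent(self):
        events = prioritize_drivers(_bundle(), CATALOG)
        assert events == []

    def test_non_catalog_gene_never_listed(self):
        bundle = _bundle({"KRAS": [_mut("KRAS", "stop_gained", "HIGH")]})
        assert prioritize_drivers(bundle, CATALOG) == []

    def test_extra_channels_add_one_each(self):
        bundle = _bundle({"ERBB2": [_mut("ERBB2", "stop_gained", "HIGH")]},
                         dereg={"ERBB2": 3.0}, methylation={"ERBB2": -2.0})
        (event,) = prioritize_drivers(bundle, CATALOG)
        # 0.8 * 3 points + 2 extra channels
        assert event.priority_score == pytest.approx(0.8 * 3 + 2)
        assert set(event.channels) == {"mutation", "expression", "methylation"}

    def test_ordering_matches_independent_scoring_oracle(self):
        rng = np.random.default_rng(23)
        catalog = [DriverCatalogEntry(f"G{i}", "oncogene", float(rng.uniform(0.5, 1.5)), "t")
                   for i in range(12)]
        grades = ["severe", "damaging", "moderate"]
        mutations, dereg = {}, {}
        for i, entry in enumerate(catalog):
            g = grades[i % 3]
            cons, imp, sift = {"severe": ("stop_gained", "HIGH", None),
                               "damaging": ("missense_variant", "MODERATE", 0.01),
                               "moderate": ("missense_variant", "MODERATE", 0.5)}[g]
            mutations[entry.gene_id] = [_mut(entry.gene_id, cons, imp, sift=sift)]
            dereg[entry.gene_id] = float(rng.normal(0, 3))
        bundle = _bundle(mutations, dereg=dereg)
        events = prioritize_drivers(bundle, catalog)
        oracle = []
        for i, entry in enumerate(catalog):
            g = grades[i % 3]
            channels = 1 + (abs(dereg[entry.gene_id]) >= 2.0)
            oracle.append((entry.gene_id,
                           entry.priority_weight * SEVERITY_POINTS[g] + channels - 1))
        oracle.sort(key=lambda t: (-t[1], t[0]))
        assert [(e.gene_id, pytest.approx(e.priority_score)) for e in events] == \
               [(g, pytest.approx(s)) for g, s in oracle]

    def test_stable_under_catalog_order_permutation(self):
        bundle = _bundle({"TP53": [_mut(consequence="stop_gained", impact="HIGH")],
                          "BRCA1": [_mut("BRCA1", "frameshift_variant", "HIGH")]})
        a = prioritize_drivers(bundle, CATALOG)
        b = prioritize_drivers(bundle, list(reversed(CATALOG)))
        assert [e.gene_id for e in a] == [e.gene_id for e in b]
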