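"""Rule-item evaluation, verdict aggregation and clinical consistency checks."""
import numpy as np
import pytest

from stratomics import assess_drug, check_consistency, evaluate_rule_item
from stratomics.bundle import OmicsBundle
from stratomics.clinical import ClinicalRecord
from stratomics.drivers import GeneCnaCall
from stratomics.expression import DeregulationScores
from stratomics.knowledge import DrugRule, RuleItem
from stratomics.variants import MutationRecord


def _mut(gene, consequence="frameshift_variant", impact="HIGH", origin="germline"):
    return MutationRecord("chr1", 10, "AT", "A", origin, gene_id=gene,
                          consequence=consequence, impact=impact)


def _bundle(clinical=None, dereg=None, mutations=None):
    return OmicsBundle(
        clinical=clinical or ClinicalRecord("P", er_status="positive",
                                            her2_status="negative"),
        deregulation=DeregulationScores(dereg if dereg is not None else {"ESR1": 0.0},
                                        "z_score"),
        mutations=mutations or {})


def _item(kind, subject, predicate, threshold=None, direction="contraindicates",
          **kwargs):
    return RuleItem(kind, subject, predicate, threshold, direction, "PMID:1", **kwargs)


class TestEvaluateRuleItem:
    def test_poor_metabolizer_fires_on_frameshift(self):
        bundle = _bundle(mutations={"CYP2D6": [_mut("CYP2D6")]})
        ev = evaluate_rule_item(_item("metabolizing_enzyme", "CYP2D6",
                                      "lof_mutation_present"), bundle, [])
        assert ev.fired and ev.direction == "contraindicates"
        assert "poor metabolizer" in ev.explanation

    def test_coregulator_overexpression_fires(self):
        bundle = _bundle(dereg={"APOBEC3B": 2.8})
        ev = evaluate_rule_item(_item("genomic_marker", "APOBEC3B",
                                      "expression_above"), bundle, [])
        assert ev.fired
        assert ev.observed_value == pytest.approx(2.8)

    def test_expression_threshold_defaults_to_z2(self):
        bundle = _bundle(dereg={"APOBEC3B": 1.5})
        ev = evaluate_rule_item(_item("genomic_marker", "APOBEC3B",
                                      "expression_above"), bundle, [])
        assert not ev.fired

    def test_missing_subject_not_assessable(self):
        bundle = _bundle(mutations={"TP53": [_mut("TP53")]})
        ev = evaluate_rule_item(_item("target", "ALK", "severity_at_most", "moderate"),
                                bundle, [])
        assert not ev.fired and not ev.assessable

    def test_severity_at_most_detects_resistance_mutation(self):
        bundle = _bundle(mutations={"ESR2": [_mut("ESR2", origin="somatic")]})
        ev = evaluate_rule_item(_item("target", "ESR2", "severity_at_most", "moderate"),
                                bundle, [])
        assert ev.fired and "resistance" in ev.explanation

    def test_status_equals_on_clinical_field(self):
        ev = evaluate_rule_item(_item("biomarker", "er_status", "status_equals",
                                      "positive", direction="supports"), _bundle(), [])
        assert ev.fired

    def test_unknown_clinical_status_not_assessable(self):
        bundle = _bundle(clinical=ClinicalRecord("P"))
        ev = evaluate_rule_item(_item("biomarker", "er_status", "status_equals",
                                      "positive"), bundle, [])
        assert not ev.assessable

    def test_fired_items_carry_evidence_ref_and_explanation(self):
        bundle = _bundle(dereg={"APOBEC3B": 3.0})
        ev = evaluate_rule_item(_item("genomic_marker", "APOBEC3B",
                                      "expression_above"), bundle, [])
        assert ev.evidence_ref and ev.explanation


class TestAssessDrug:
    def _tamoxifen_like(self):
        return DrugRule("tamx", "Tamx", "soc", [
            _item("biomarker", "er_status", "status_equals", "positive",
                  direction="supports"),
            _item("metabolizing_enzyme", "CYP2D6", "lof_mutation_present"),
            _item("target", "ESR2", "severity_at_most", "moderate"),
        ])

    def test_enzyme_contraindication_is_decisive(self):
        bundle = _bundle(mutations={"CYP2D6": [_mut("CYP2D6")]})
        a = assess_drug(self._tamoxifen_like(), bundle, [])
        assert a.verdict == "contraindicated"
        assert a.n_supporting == 1 and a.n_contra == 1

    def test_support_only_suggested(self):
        bundle = _bundle(mutations={"TP53": [_mut("TP53", origin="somatic")]})
        a = assess_drug(self._tamoxifen_like(), bundle, [])
        assert a.verdict == "suggested"

    def test_nondecisive_biomarker_downgrades_to_conditional(self):
        rule = DrugRule("ai", "AI", "soc", [
            _item("biomarker", "er_status", "status_equals", "positive",
                  direction="supports"),
            _item("biomarker", "menopausal_status", "status_equals", "pre",
                  decisive=False),
        ])
        bundle = _bundle(clinical=ClinicalRecord("P", er_status="positive",
                                                 menopausal_status="pre"))
        a = assess_drug(rule, bundle, [])
        assert a.verdict == "conditional"

    def test_two_soft_contraindications_reach_contraindicated(self):
        rule = DrugRule("d", "D", "soc", [
            _item("genomic_marker", "APOBEC3B", "expression_above"),
            _item("target", "ESR2", "severity_at_most", "moderate"),
        ])
        bundle = _bundle(dereg={"APOBEC3B": 3.0},
                         mutations={"ESR2": [_mut("ESR2", origin="somatic")]})
        a = assess_drug(rule, bundle, [])
        assert a.verdict == "contraindicated"

    def test_empty_bundle_not_assessable(self, kb):
        bundle = OmicsBundle(clinical=ClinicalRecord("P"),
                             deregulation=DeregulationScores({}, "z_score"))
        for rule in kb.soc_drugs + kb.driver_targeting_drugs:
            assert assess_drug(rule, bundle, []).verdict == "not_assessable"

    def test_pure_function_of_inputs(self):
        bundle = _bundle(mutations={"CYP2D6": [_mut("CYP2D6")]})
        rule = self._tamoxifen_like()
        a = assess_drug(rule, bundle, [])
        b = assess_drug(rule, bundle, [])
        assert a.to_dict() == b.to_dict()

    def test_unrelated_gene_does_not_change_assessment(self):
        rule = self._tamoxifen_like()
        base = _bundle(mutations={"CYP2D6": [_mut("CYP2D6")]})
        extended = _bundle(dereg={"ESR1": 0.0, "SYN0001": 5.0},
                           mutations={"CYP2D6": [_mut("CYP2D6")],
                                      "KRAS": [_mut("KRAS", origin="somatic")]})
        assert assess_drug(rule, base, []).verdict == \
            assess_drug(rule, extended, []).verdict


class TestCheckConsistency:
    def test_her2_negative_but_erbb2_overexpressed(self):
        bundle = _bundle(dereg={"ERBB2": 4.0})
        warnings = check_consistency(bundle)
        assert len(warnings) == 1
        assert "ERBB2" in warnings[0]

    def test_concordant_bundle_yields_no_warnings(self):
        bundle = _bundle(dereg={"ERBB2": 0.2, "ESR1": 0.5, "PGR": -0.3})
        assert check_consistency(bundle) == []

    def test_cna_amplification_conflict(self):
        bundle = _bundle(dereg={"ERBB2": 0.0})
        warnings = check_consistency(bundle, [GeneCnaCall("ERBB2", 1.1, "amplified")])
        assert any("amplified" in w for w in warnings)

    def test_randomized_fixtures_match_recheck_oracle(self):
        rng = np.random.default_rng(31)
        for _ in range(25):
            status = {f: ["positive", "negative", "unknown"][int(rng.integers(3))]
                      for f in ("er_status", "pr_status", "her2_status")}
            scores = {g: float(rng.normal(0, 2.5))
                      for g in ("ERBB2", "ESR1", "PGR")}
            bundle = _bundle(clinical=ClinicalRecord("P", **status), dereg=scores)
            expected = 0
            for f, g in (("her2_status", "ERBB2"), ("er_status", "ESR1"),
                         ("pr_status", "PGR")):
                if status[f] == "negative" and scores[g] >= 2.0:
                    expected += 1
                if status[f] == "positive" and scores[g] <= -2.0:
                    expected += 1
            assert len(check_consistency(bundle)) == expected
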