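"""Rule-based drug assessment.

Each drug carries a list of declarative rule items (biomarkers, molecular
targets, metabolizing enzymes, efflux transporters, pathways, genomic
markers) with closed-vocabulary predicates. Evaluation is a pure function of
the knowledge bundle, the omics bundle and the pathway activities.

Verdict aggregation (an explicit surrogate; the published presentation lists
per-factor indicators without combining them):

* ``contraindicated`` — any fired *decisive* contraindication of kind
  biomarker or metabolizing_enzyme (these act as gatekeepers: receptor status
  for endocrine therapy, prodrug activation), or >=2 fired contraindications
  of any kind;
* ``suggested`` — >=1 fired support and no fired contraindication;
* ``conditional`` — supports and contraindications both fired, below the
  contraindicated bar;
* ``not_assessable`` — no rule item could be evaluated.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

from .bundle import OmicsBundle
from .drivers import (GeneCnaCall, SEVERITY_ORDER, best_grade, cna_call_map,
                      DEREGULATION_THRESHOLD)
from .errors import InputError
from .expression import LOG_FOLD_CHANGE
from .knowledge import DrugRule, RuleItem
from .pathways import PathwayActivityResult

# "highly expressed" defaults: z >= 2, or log2 fold-change >= 1
HIGH_Z, HIGH_LFC = 2.0, 1.0


@dataclass
class EvidenceItem:
    kind: str
    subject: str
    predicate: str
    direction: str
    fired: bool
    assessable: bool
    observed_value: object
    explanation: str
    evidence_ref: str
    decisive: bool = True

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("kind", "subject", "predicate", "direction", "fired", "assessable",
                 "observed_value", "explanation", "evidence_ref", "decisive")}


@dataclass
class DrugAssessment:
    drug_id: str
    drug_name: str
    category: str
    verdict: str
    n_supporting: int
    n_contra: int
    items: List[EvidenceItem]
    consistency_warnings: List[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"drug_id": self.drug_id, "drug_name": self.drug_name,
                "category": self.category, "verdict": self.verdict,
                "n_supporting": self.n_supporting, "n_contra": self.n_contra,
                "items": [i.to_dict() for i in self.items],
                "consistency_warnings": self.consistency_warnings}


def _expression_thresholds(bundle: OmicsBundle) -> float:
    if bundle.deregulation is not None and bundle.deregulation.score_kind == LOG_FOLD_CHANGE:
        return HIGH_LFC
    return HIGH_Z


def _not_assessable(item: RuleItem, why: str) -> EvidenceItem:
    return EvidenceItem(item.kind, item.subject, item.predicate, item.direction,
                        fired=False, assessable=False, observed_value=None,
                        explanation=f"not assessable: {why}",
                        evidence_ref=item.evidence_ref, decisive=item.decisive)


def evaluate_rule_item(item: RuleItem, bundle: OmicsBundle,
                       activities: Sequence[PathwayActivityResult]) -> EvidenceItem:
    """Dispatch one rule item against the omics bundle / pathway activities."""
    pred = item.predicate
    fired = False
    observed: object = None
    explanation = ""

    if pred == "status_equals":
        value = getattr(bundle.clinical, item.subject, None)
        if value is None:
            return _not_assessable(item, f"clinical field {item.subject!r} missing")
        if value == "unknown":
            return _not_assessable(item, f"clinical {item.subject} unknown")
        observed = value
        fired = value == item.threshold
        explanation = f"clinical {item.subject} is {value}"
        if item.subject == "menopausal_status" and fired and not item.decisive:
            explanation += " (consider ovary suppression alongside)"
    elif pred in ("expression_above", "expression_below"):
        if bundle.deregulation is None:
            return _not_assessable(item, "no expression data")
        score = bundle.deregulation.get(item.subject)
        if score is None:
            return _not_assessable(item, f"{item.subject} not in expression data")
        thr = float(item.threshold) if item.threshold is not None \
            else _expression_thresholds(bundle)
        observed = score
        if pred == "expression_above":
            fired = score >= thr
            explanation = f"{item.subject} deregulation {score:.2f} vs threshold {thr:g}"
        else:
            fired = score <= -thr
            explanation = f"{item.subject} deregulation {score:.2f} vs threshold -{thr:g}"
    elif pred in ("lof_mutation_present", "any_mutation_present", "mutation_absent",
                  "severity_at_most"):
        muts = bundle.mutations_for(item.subject)
        if not muts:
            if not bundle.mutations:
                return _not_assessable(item, "no mutation data")
            if item.subject not in bundle.genes():
                return _not_assessable(item, f"{item.subject} absent from every channel")
        grade = best_grade(muts)
        observed = grade if muts else "no mutation"
        if pred == "lof_mutation_present":
            fired = grade == "severe"
            explanation = (f"{item.subject} carries a function-destroying mutation "
                           f"(grade {grade})" if fired else
                           f"no loss-of-function mutation in {item.subject}")
            if fired and item.kind == "metabolizing_enzyme":
                explanation = (f"{item.subject} loss-of-function: likely poor metabolizer "
                               f"phenotype (grade {grade})")
        elif pred == "any_mutation_present":
            fired = bool(muts)
            explanation = (f"{item.subject} mutated (grade {grade})" if fired
                           else f"{item.subject} not mutated")
        elif pred == "mutation_absent":
            fired = SEVERITY_ORDER.index(grade) < SEVERITY_ORDER.index("moderate")
            explanation = (f"no consequential mutation in {item.subject}" if fired
                           else f"{item.subject} mutated (grade {grade})")
        else:  # severity_at_most: fires when the observed grade EXCEEDS the bar
            allowed = str(item.threshold)
            if allowed not in SEVERITY_ORDER:
                raise InputError(f"severity_at_most: unknown grade {allowed!r}")
            fired = SEVERITY_ORDER.index(grade) > SEVERITY_ORDER.index(allowed)
            explanation = (f"{item.subject} mutation grade {grade} exceeds allowed "
                           f"{allowed} (possible resistance mutation)" if fired else
                           f"{item.subject} mutation grade {grade} within allowed {allowed}")
    elif pred == "copy_number_above":
        if not bundle.cna:
            return _not_assessable(item, "no copy-number data")
        lr = bundle.cna.get(item.subject)
        if lr is None:
            return _not_assessable(item, f"{item.subject} not covered by segments")
        observed = lr
        fired = lr >= float(item.threshold)
        explanation = f"{item.subject} copy-number log-ratio {lr:.2f} vs {item.threshold:g}"
    elif pred == "activity_label_in":
        res = next((r for r in activities if r.pathway_id == item.subject), None)
        if res is None or not res.assessable:
            return _not_assessable(item, f"pathway {item.subject} not assessable")
        observed = res.label
        wanted = [item.threshold] if isinstance(item.threshold, str) else list(item.threshold)
        fired = res.label in wanted
        explanation = f"pathway {item.subject} activity label {res.label}"
    else:  # pragma: no cover - schema validation rejects unknown predicates
        raise InputError(f"unknown predicate {pred!r}")

    return EvidenceItem(item.kind, item.subject, item.predicate, item.direction,
                        fired=fired, assessable=True, observed_value=observed,
                        explanation=explanation, evidence_ref=item.evidence_ref,
                        decisive=item.decisive)


def assess_drug(rule: DrugRule, bundle: OmicsBundle,
                activities: Sequence[PathwayActivityResult]) -> DrugAssessment:
    items = [evaluate_rule_item(it, bundle, activities) for it in rule.rule_items]
    fired_support = [i for i in items if i.fired and i.direction == "supports"]
    fired_contra = [i for i in items if i.fired and i.direction == "contraindicates"]
    decisive_contra = [i for i in fired_contra if i.decisive and
                       i.kind in ("biomarker", "metabolizing_enzyme")]
    if not any(i.assessable for i in items):
        verdict = "not_assessable"
    elif decisive_contra or len(fired_contra) >= 2:
        verdict = "contraindicated"
    elif fired_support and not fired_contra:
        verdict = "suggested"
    elif fired_support and fired_contra:
        verdict = "conditional"
    elif fired_contra:
        verdict = "conditional"
    else:
        verdict = "not_assessable" if not fired_support else "suggested"
    return DrugAssessment(rule.drug_id, rule.drug_name, rule.category, verdict,
                          len(fired_support), len(fired_contra), items)


def assess_soc(rules: Sequence[DrugRule], bundle: OmicsBundle,
               activities: Sequence[PathwayActivityResult]) -> List[DrugAssessment]:
    return [assess_drug(r, bundle, activities) for r in rules if r.category == "soc"]


def assess_driver_targeting(rules: Sequence[DrugRule], bundle: OmicsBundle,
                            activities: Sequence[PathwayActivityResult]
                            ) -> List[DrugAssessment]:
    """Off-label candidates: same machinery, labeled driver_targeting."""
    return [assess_drug(r, bundle, activities)
            for r in rules if r.category == "driver_targeting"]


def check_consistency(bundle: OmicsBundle,
                      cna_calls: Optional[Sequence[GeneCnaCall]] = None) -> List[str]:
    """Compare clinical receptor status against expression and copy number."""
    warnings: List[str] = []
    calls = cna_call_map(cna_calls or [])
    thr = _expression_thresholds(bundle)

    def dereg(gene):
        return bundle.deregulation.get(gene) if bundle.deregulation else None

    checks = [("her2_status", "ERBB2"), ("er_status", "ESR1"), ("pr_status", "PGR")]
    for status_field, gene in checks:
        status = getattr(bundle.clinical, status_field)
        score = dereg(gene)
        call = calls.get(gene)
        if status == "negative":
            if score is not None and score >= thr:
                warnings.append(f"clinical {status_field} negative but {gene} strongly "
                                f"overexpressed (score {score:.2f})")
            if call is not None and call.call == "amplified":
                warnings.append(f"clinical {status_field} negative but {gene} amplified "
                                f"(log-ratio {call.log_ratio:.2f})")
        elif status == "positive":
            if score is not None and score <= -thr:
                warnings.append(f"clinical {status_field} positive but {gene} strongly "
                                f"downregulated (score {score:.2f})")
            if call is not None and call.call == "deleted":
                warnings.append(f"clinical {status_field} positive but {gene} deleted "
                                f"(log-ratio {call.log_ratio:.2f})")
    return warnings
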