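"""The PAD risk-scoring engine.

For an eligible, censored record the total score decomposes into

* an antibiotic block: each prescription of a listed ATC code in the 4-year
  window before the censoring date (and on/after the patient's 6th birthday)
  contributes its rule weight; when the patient was enrolled for fewer than
  4 x 365 days before censoring the weighted sum is scaled by
  ``4 / (days_enrolled / 365)`` to normalize for observation time;
* five ICPC category blocks: a rule contributes its weight once if any of
  its codes appears within the category's look-back window (10 years for
  respiratory-tract and gastro-intestinal complaints, lifetime otherwise);
* a laboratory block: each analyte rule contributes once if any result is
  strictly below its threshold;
* a visit block: the visit-rule weight if the 1-year contact count reaches
  the cut-off.

All windows are half-open at the far end and inclusive at the censoring
date: ``(censor - N days, censor]``, with a 365-day year throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Iterable, Optional, Sequence, Union

from .censoring import (
    CensoredRecord,
    EligibilityResult,
    check_eligibility,
    determine_censoring_date,
    truncate,
)
from .ehr_model import PatientRecord, age_in_years
from .errors import DataError
from .ruleset import Category, RuleSet

__all__ = [
    "ScreeningResult",
    "FlagRule",
    "antibiotic_score",
    "icpc_category_score",
    "lab_score",
    "visit_score",
    "score_patient",
    "screen_cohort",
]

log = logging.getLogger(__name__)

DAYS_PER_YEAR = 365


@dataclass
class ScreeningResult:
    """Per-patient screening output.

    ``fired_components`` lists every component that contributed points, as
    (component_id, points) pairs; within each block the points sum to the
    block subscore, and the subscores sum to ``total_score``.
    """

    patient_id: str
    censoring_date: date
    eligibility: EligibilityResult
    antibiotic_score: float = 0.0
    category_scores: dict[Category, float] = field(default_factory=dict)
    lab_score: float = 0.0
    visit_score: float = 0.0
    total_score: Optional[float] = None
    fired_components: list[tuple[str, float]] = field(default_factory=list)
    flagged: bool = False

    def as_row(self) -> dict:
        row = {
            "patient_id": self.patient_id,
            "censoring_date": self.censoring_date.isoformat(),
            "eligible": str(self.eligibility.eligible).lower(),
            "exclusion_reason": ""
            if self.eligibility.eligible
            else self.eligibility.reason.value,
        }
        if self.eligibility.eligible:
            row["antibiotic_score"] = self.antibiotic_score
            for cat in Category:
                row[f"{cat.value}_score"] = self.category_scores.get(cat, 0.0)
            row["lab_score"] = self.lab_score
            row["visit_score"] = self.visit_score
            row["total_score"] = self.total_score
        else:
            row["antibiotic_score"] = ""
            for cat in Category:
                row[f"{cat.value}_score"] = ""
            row["lab_score"] = ""
            row["visit_score"] = ""
            row["total_score"] = ""
        return row


def _in_window(d: date, censoring_date: date, window_days: Optional[int]) -> bool:
    if d > censoring_date:
        return False
    if window_days is None:
        return True
    return d > censoring_date - timedelta(days=window_days)


def days_enrolled(record: PatientRecord, censoring_date: date) -> int:
    """Observable enrollment days before censoring: enrollment_start to
    min(censoring_date, enrollment_end)."""
    end = censoring_date
    if record.enrollment_end is not None and record.enrollment_end < end:
        end = record.enrollment_end
    return (end - record.enrollment_start).days


def antibiotic_score(
    record: PatientRecord,
    censoring_date: date,
    ruleset: RuleSet,
    fired: Optional[list[tuple[str, float]]] = None,
) -> float:
    """Weighted antibiotic prescription score over the 4-year window, with
    enrollment-time normalization for patients observed under 4 x 365 days.

    Each prescription counts individually (repeats accumulate); prescriptions
    before the patient's 6th birthday are ignored.
    """
    window_days = ruleset.antibiotic_window_years * DAYS_PER_YEAR
    weights = ruleset.antibiotic_weights
    min_age = ruleset.antibiotic_min_age_years
    per_component: dict[str, float] = {}
    raw = 0.0
    for e in record.prescriptions:
        w = weights.get(e.atc_code)
        if w is None:
            continue
        if not _in_window(e.date, censoring_date, window_days):
            continue
        if age_in_years(record.birth_date, e.date) < min_age:
            continue
        raw += w
        cid = f"abx:{e.atc_code}"
        per_component[cid] = per_component.get(cid, 0.0) + w

    enrolled = days_enrolled(record, censoring_date)
    if enrolled <= 0:
        raise DataError(
            f"patient {record.patient_id}: no observable enrollment before "
            f"{censoring_date} (days_enrolled={enrolled})"
        )
    factor = 1.0
    if enrolled < window_days:
        if enrolled < 90:
            log.warning(
                "patient %s enrolled only %d days before censoring; "
                "normalized antibiotic score is an unstable extrapolation",
                record.patient_id,
                enrolled,
            )
        factor = ruleset.antibiotic_window_years / (enrolled / DAYS_PER_YEAR)
    if fired is not None:
        for cid in sorted(per_component):
            fired.append((cid, per_component[cid] * factor))
    return raw * factor


def icpc_category_score(
    record: PatientRecord,
    censoring_date: date,
    category: Union[Category, str],
    ruleset: RuleSet,
    fired: Optional[list[tuple[str, float]]] = None,
) -> float:
    """Presence score for one ICPC category: each rule fires at most once if
    any of its codes occurs within the category window."""
    category = Category(category)
    window_days = ruleset.window_days(category)
    present = {
        e.icpc_code
        for e in record.diagnoses
        if _in_window(e.date, censoring_date, window_days)
    }
    total = 0.0
    for rule in ruleset.icpc_categories[category]:
        if any(code in present for code in rule.codes):
            total += rule.weight
            if fired is not None:
                fired.append((rule.component_id, rule.weight))
    return total


def lab_score(
    record: PatientRecord,
    censoring_date: date,
    ruleset: RuleSet,
    fired: Optional[list[tuple[str, float]]] = None,
) -> float:
    """Laboratory score: each analyte rule fires at most once if any result
    on/before the censoring date is strictly below its threshold."""
    total = 0.0
    for rule in ruleset.labs:
        hit = any(
            lab.analyte is rule.analyte
            and lab.date <= censoring_date
            and lab.value < rule.threshold
            for lab in record.labs
        )
        if hit:
            total += rule.weight
            if fired is not None:
                fired.append((rule.component_id, rule.weight))
    return total


def visit_count(record: PatientRecord, censoring_date: date, window_days: int) -> int:
    return sum(
        1 for v in record.visits if _in_window(v.date, censoring_date, window_days)
    )


def visit_score(
    record: PatientRecord,
    censoring_date: date,
    ruleset: RuleSet,
    fired: Optional[list[tuple[str, float]]] = None,
) -> float:
    """Visit-rule weight if GP contacts (both modalities) in the window reach
    the cut-off, else 0."""
    rule = ruleset.visits
    n = visit_count(record, censoring_date, rule.window_days)
    if n >= rule.cutoff:
        if fired is not None:
            fired.append((rule.component_id, rule.weight))
        return rule.weight
    return 0.0


def score_patient(
    record: PatientRecord, run_date: date, ruleset: RuleSet
) -> ScreeningResult:
    """Full pipeline for one patient: censoring, eligibility, truncation and
    the four scoring blocks. Ineligible patients get no scores."""
    censored = determine_censoring_date(record, run_date, ruleset)
    eligibility = check_eligibility(record, censored, ruleset)
    result = ScreeningResult(
        patient_id=record.patient_id,
        censoring_date=censored.censoring_date,
        eligibility=eligibility,
    )
    if not eligibility.eligible:
        return result

    truncated = truncate(record, censored)
    fired: list[tuple[str, float]] = []
    result.antibiotic_score = antibiotic_score(
        truncated, censored.censoring_date, ruleset, fired
    )
    for cat in Category:
        if cat in ruleset.icpc_categories:
            result.category_scores[cat] = icpc_category_score(
                truncated, censored.censoring_date, cat, ruleset, fired
            )
    result.lab_score = lab_score(truncated, censored.censoring_date, ruleset, fired)
    result.visit_score = visit_score(truncated, censored.censoring_date, ruleset, fired)
    result.total_score = (
        result.antibiotic_score
        + sum(result.category_scores.values())
        + result.lab_score
        + result.visit_score
    )
    result.fired_components = fired
    return result


@dataclass(frozen=True)
class FlagRule:
    """Who gets flagged for laboratory follow-up: the top *k* scorers, or
    everyone at/above a score *threshold*. Exactly one must be given."""

    top_k: Optional[int] = None
    threshold: Optional[float] = None

    def __post_init__(self):
        if (self.top_k is None) == (self.threshold is None):
            raise ValueError("specify exactly one of top_k or threshold")
        if self.top_k is not None and self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.threshold is not None and self.threshold < 0:
            raise ValueError("threshold must be >= 0")


def screen_cohort(
    records: Iterable[PatientRecord],
    run_date: date,
    ruleset: RuleSet,
    flag_rule: FlagRule,
) -> list[ScreeningResult]:
    """Score a cohort, rank eligible patients by total score (descending,
    ties broken by patient_id ascending) and mark the flagged subset.
    Ineligible patients are appended after the ranked list, unflagged."""
    results = [score_patient(rec, run_date, ruleset) for rec in records]
    eligible = [r for r in results if r.eligibility.eligible]
    ineligible = [r for r in results if not r.eligibility.eligible]
    eligible.sort(key=lambda r: (-r.total_score, r.patient_id))
    ineligible.sort(key=lambda r: r.patient_id)
    if flag_rule.top_k is not None:
        for r in eligible[: flag_rule.top_k]:
            r.flagged = True
    else:
        for r in eligible:
            if r.total_score >= flag_rule.threshold:
                r.flagged = True
    return eligible + ineligible
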