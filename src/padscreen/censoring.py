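"""Censoring dates, eligibility and record truncation.

A patient's record is screened up to a *censoring date*: normally the run
(extraction) date, but if the record ever carries an ambiguous diagnosis —
one that can be either a complication of an antibody deficiency or a cause
of a secondary one (e.g. non-Hodgkin lymphoma) — the earliest such diagnosis
date censors the record instead. Events dated exactly on the censoring date
are included, so an ambiguous code that also carries a score contributes it.

Eligibility is checked on the *untruncated* record: an exclusion diagnosis
(a cause of secondary antibody deficiency) at any time removes the patient,
as does an age outside the configured bounds at the censoring date. When a
patient has both an exclusion and an ambiguous code, exclusion wins.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from enum import Enum

from .ehr_model import PatientRecord
from .ruleset import RuleSet

__all__ = [
    "CensoredBy",
    "IneligibilityReason",
    "CensoredRecord",
    "EligibilityResult",
    "determine_censoring_date",
    "check_eligibility",
    "truncate",
]


class CensoredBy(str, Enum):
    run_date = "run_date"
    ambiguous_diagnosis = "ambiguous_diagnosis"


class IneligibilityReason(str, Enum):
    ok = "ok"
    age_below_min = "age_below_min"
    age_above_max = "age_above_max"
    exclusion_code = "exclusion_code"


@dataclass(frozen=True)
class CensoredRecord:
    source: PatientRecord
    censoring_date: date
    censored_by: CensoredBy
    ambiguous_code: str = ""


@dataclass(frozen=True)
class EligibilityResult:
    eligible: bool
    reason: IneligibilityReason
    triggering_code: str = ""

    def __post_init__(self):
        assert self.eligible == (self.reason is IneligibilityReason.ok)


def determine_censoring_date(
    record: PatientRecord, run_date: date, ruleset: RuleSet
) -> CensoredRecord:
    """Earliest ambiguous diagnosis on or before *run_date*, else *run_date*."""
    ambiguous = ruleset.ambiguous_codes
    hits = [
        e for e in record.diagnoses if e.icpc_code in ambiguous and e.date <= run_date
    ]
    if hits:
        first = min(hits, key=lambda e: (e.date, e.icpc_code))
        return CensoredRecord(
            source=record,
            censoring_date=first.date,
            censored_by=CensoredBy.ambiguous_diagnosis,
            ambiguous_code=first.icpc_code,
        )
    return CensoredRecord(
        source=record, censoring_date=run_date, censored_by=CensoredBy.run_date
    )


def check_eligibility(
    record: PatientRecord, censored: CensoredRecord, ruleset: RuleSet
) -> EligibilityResult:
    """Exclusion codes (any date, untruncated record) and age bounds at the
    censoring date. The first matching exclusion code (by date, then code)
    is reported."""
    exclusions = ruleset.exclusion_codes
    hits = [e for e in record.diagnoses if e.icpc_code in exclusions]
    if hits:
        first = min(hits, key=lambda e: (e.date, e.icpc_code))
        return EligibilityResult(
            eligible=False,
            reason=IneligibilityReason.exclusion_code,
            triggering_code=first.icpc_code,
        )
    age = record.age_at(censored.censoring_date)
    if age < ruleset.age_bounds.min:
        return EligibilityResult(False, IneligibilityReason.age_below_min)
    if age > ruleset.age_bounds.max:
        return EligibilityResult(False, IneligibilityReason.age_above_max)
    return EligibilityResult(True, IneligibilityReason.ok)


def truncate(record: PatientRecord, censored: CensoredRecord) -> PatientRecord:
    """Record view with only events dated on or before the censoring date."""
    return record.truncated(censored.censoring_date)
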