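"""Component-selection and descriptive statistics.

These are the tools used to choose and weight algorithm components from
case/control cohorts: per-component sensitivity in two case groups (confirmed
PAD and primary-care immunodeficiency), specificity in a general-population
control group, Youden's index on the mean sensitivity, cut-off sweeps for
count-valued features, per-group descriptive summaries (per-year antibiotic
prescription means, 4-year totals, 1-year visit medians, sparse lab-value
summaries), and coded-vs-free-text concordance.

Youden's index here is ``J = mean(sens_pad, sens_pcid) + specificity - 1``,
with sensitivities averaged over the two case groups because neither alone
is large enough to anchor component choice.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta
from typing import Callable, Mapping, Optional, Sequence, Union

import numpy as np

from .censoring import determine_censoring_date, truncate
from .ehr_model import Analyte, PatientRecord, age_in_years
from .errors import DataError, RuleSetError
from .ruleset import AntibioticRule, Category, IcpcRule, LabRule, RuleSet, VisitRule
from .scoring import DAYS_PER_YEAR, _in_window, visit_count

__all__ = [
    "ComponentDiagnostics",
    "GroupSummary",
    "ConcordanceResult",
    "component_presence",
    "youden_index",
    "cutoff_sweep",
    "group_summary",
    "concordance",
]


@dataclass(frozen=True)
class ComponentDiagnostics:
    component_id: str
    sensitivity_pad: float
    sensitivity_pcid: float
    specificity: float

    @property
    def mean_sensitivity(self) -> float:
        return (self.sensitivity_pad + self.sensitivity_pcid) / 2

    @property
    def youden(self) -> float:
        return self.mean_sensitivity + self.specificity - 1


def component_presence(
    record: PatientRecord,
    censoring_date: date,
    component_id: str,
    ruleset: RuleSet,
) -> bool:
    """Would this component fire for a censored+truncated record?

    Antibiotic components: at least one prescription of the code in the
    4-year window at/after age 6. ICPC components: any of the rule's codes
    within the category window. Lab components: any result strictly below the
    threshold. The visit component: count >= cut-off in the 1-year window.
    """
    rule = ruleset.find_component(component_id)
    if isinstance(rule, AntibioticRule):
        window = ruleset.antibiotic_window_years * DAYS_PER_YEAR
        return any(
            e.atc_code == rule.atc
            and _in_window(e.date, censoring_date, window)
            and age_in_years(record.birth_date, e.date) >= ruleset.antibiotic_min_age_years
            for e in record.prescriptions
        )
    if isinstance(rule, IcpcRule):
        window = ruleset.window_days(ruleset.icpc_rule_category(rule))
        return any(
            e.icpc_code in rule.codes and _in_window(e.date, censoring_date, window)
            for e in record.diagnoses
        )
    if isinstance(rule, LabRule):
        return any(
            lab.analyte is rule.analyte
            and lab.date <= censoring_date
            and lab.value < rule.threshold
            for lab in record.labs
        )
    if isinstance(rule, VisitRule):
        return visit_count(record, censoring_date, rule.window_days) >= rule.cutoff
    raise RuleSetError(f"unknown component kind for {component_id!r}")


CensoringDates = Union[date, Mapping[str, date]]


def _censoring_date_for(
    record: PatientRecord, when: CensoringDates, ruleset: RuleSet
) -> date:
    """Resolve a patient's censoring date.

    *when* may be a single run date for the whole cohort or a mapping
    patient_id -> date (e.g. diagnosis dates for pre-diagnosis analyses of
    case groups); records carrying a ``diagnosis_date`` fall back to it when
    absent from the mapping. Ambiguous-diagnosis censoring still applies on
    top of the resolved date.
    """
    if isinstance(when, Mapping):
        d = when.get(record.patient_id, record.diagnosis_date)
        if d is None:
            raise DataError(
                f"no censoring/run date for patient {record.patient_id}"
            )
    else:
        d = when
    return determine_censoring_date(record, d, ruleset).censoring_date


def _presence_fraction(
    cohort: Sequence[PatientRecord],
    when: CensoringDates,
    component_id: str,
    ruleset: RuleSet,
    name: str,
) -> float:
    if not cohort:
        raise DataError(f"cohort {name!r} is empty")
    hits = 0
    for rec in cohort:
        cdate = _censoring_date_for(rec, when, ruleset)
        truncated = rec.truncated(cdate)
        if component_presence(truncated, cdate, component_id, ruleset):
            hits += 1
    return hits / len(cohort)


def youden_index(
    pad_cases: Sequence[PatientRecord],
    pcid_cases: Sequence[PatientRecord],
    controls: Sequence[PatientRecord],
    component_id: str,
    ruleset: RuleSet,
    *,
    case_dates: Optional[CensoringDates] = None,
    control_dates: Optional[CensoringDates] = None,
    run_date: Optional[date] = None,
) -> ComponentDiagnostics:
    """Sensitivity in each case group, specificity in controls, and Youden's
    index for one component. Case groups default to diagnosis-date censoring
    (pre-diagnosis records); controls default to the run date."""
    if run_date is None:
        run_date = date.today()
    case_when = case_dates if case_dates is not None else {}
    control_when = control_dates if control_dates is not None else run_date
    sens_pad = _presence_fraction(pad_cases, case_when, component_id, ruleset, "pad_cases")
    sens_pcid = _presence_fraction(
        pcid_cases, case_when, component_id, ruleset, "pcid_cases"
    )
    fpr = _presence_fraction(controls, control_when, component_id, ruleset, "controls")
    return ComponentDiagnostics(
        component_id=component_id,
        sensitivity_pad=sens_pad,
        sensitivity_pcid=sens_pcid,
        specificity=1 - fpr,
    )


CountFeature = Union[str, Callable[[PatientRecord, date], int]]


def _count_feature_fn(feature: CountFeature, window_days: int):
    if callable(feature):
        return feature
    if feature == "visits":
        return lambda rec, cdate: visit_count(rec, cdate, window_days)
    raise RuleSetError(
        f"count feature {feature!r} is not derivable from the cohort tables; "
        "pass a counting function (record, censoring_date) -> int"
    )


@dataclass(frozen=True)
class SweepResult:
    table: tuple[tuple[int, ComponentDiagnostics], ...]
    selected_cutoff: int


def cutoff_sweep(
    pad_cases: Sequence[PatientRecord],
    pcid_cases: Sequence[PatientRecord],
    controls: Sequence[PatientRecord],
    count_feature: CountFeature,
    ruleset: RuleSet,
    candidate_cutoffs: Optional[Sequence[int]] = None,
    *,
    window_days: int = 365,
    case_dates: Optional[CensoringDates] = None,
    control_dates: Optional[CensoringDates] = None,
    run_date: Optional[date] = None,
) -> SweepResult:
    """Youden's index of the binary feature "count >= c in the 1-year window"
    for each candidate cut-off c; the selected cut-off maximizes Youden's
    index, ties broken toward the smallest cut-off.

    When no candidates are given, the integer range [median - 3, median + 3]
    around the PAD-group median count (clipped below at 1) is swept.
    """
    if run_date is None:
        run_date = date.today()
    fn = _count_feature_fn(count_feature, window_days)
    case_when = case_dates if case_dates is not None else {}
    control_when = control_dates if control_dates is not None else run_date

    def counts(cohort, when, name):
        if not cohort:
            raise DataError(f"cohort {name!r} is empty")
        out = []
        for rec in cohort:
            cdate = _censoring_date_for(rec, when, ruleset)
            out.append(fn(rec.truncated(cdate), cdate))
        return np.asarray(out)

    pad_counts = counts(pad_cases, case_when, "pad_cases")
    pcid_counts = counts(pcid_cases, case_when, "pcid_cases")
    control_counts = counts(controls, control_when, "controls")

    if candidate_cutoffs is None:
        med = int(round(float(np.median(pad_counts))))
        candidate_cutoffs = [c for c in range(med - 3, med + 4) if c >= 1]
    if not candidate_cutoffs:
        raise DataError("no candidate cut-offs to sweep")
    if any(c < 1 for c in candidate_cutoffs):
        raise DataError("candidate cut-offs must be positive integers")

    rows = []
    for c in sorted(set(int(c) for c in candidate_cutoffs)):
        diag = ComponentDiagnostics(
            component_id=f"count>={c}",
            sensitivity_pad=float(np.mean(pad_counts >= c)),
            sensitivity_pcid=float(np.mean(pcid_counts >= c)),
            specificity=float(np.mean(control_counts < c)),
        )
        rows.append((c, diag))
    selected = max(rows, key=lambda r: (r[1].youden, -r[0]))[0]
    return SweepResult(table=tuple(rows), selected_cutoff=selected)


@dataclass(frozen=True)
class LabSummary:
    mean: Optional[float]  # None when no patient has a result ("-")
    sd: Optional[float]
    n: int  # patients with at least one result


@dataclass(frozen=True)
class GroupSummary:
    label: str
    n: int
    prescriptions_per_year: tuple[float, ...]  # years -10..-1 before censoring
    mean_4y_prescriptions: float
    median_1y_visits: float
    labs: dict[Analyte, LabSummary]


def group_summary(
    cohort: Sequence[PatientRecord],
    when: CensoringDates,
    ruleset: RuleSet,
    *,
    label: str = "",
    lab_window_years: int = 10,
) -> GroupSummary:
    """Descriptive summary of one patient group.

    Per-year antibiotic prescription means use year bins
    ``(censor - k*365, censor - (k-1)*365]`` for k = 10..1; the 4-year mean
    total counts prescriptions of listed antibiotics in the last four bins.
    Visit medians use the 1-year window. Lab means/SDs pool all results in
    the 10 years before censoring, per analyte, over patients with at least
    one result (n reports that patient count; analytes never requested are
    reported with mean/sd None, the "-" convention).
    """
    if not cohort:
        raise DataError("cannot summarize an empty cohort")
    abx_codes = set(ruleset.antibiotic_weights)
    per_year = np.zeros((len(cohort), 10))
    totals_4y = np.zeros(len(cohort))
    visits_1y = np.zeros(len(cohort))
    lab_values: dict[Analyte, list[float]] = {a: [] for a in Analyte}
    lab_patients: dict[Analyte, set[str]] = {a: set() for a in Analyte}

    for i, rec in enumerate(cohort):
        cdate = _censoring_date_for(rec, when, ruleset)
        truncated = rec.truncated(cdate)
        for e in truncated.prescriptions:
            if e.atc_code not in abx_codes:
                continue
            delta = (cdate - e.date).days
            if delta < 0:
                continue
            k = delta // DAYS_PER_YEAR + 1  # year bin, 1 = nearest
            if k <= 10:
                per_year[i, 10 - k] += 1
            if k <= ruleset.antibiotic_window_years:
                totals_4y[i] += 1
        visits_1y[i] = visit_count(truncated, cdate, ruleset.visits.window_days)
        lab_window = lab_window_years * DAYS_PER_YEAR
        for lab in truncated.labs:
            if _in_window(lab.date, cdate, lab_window):
                lab_values[lab.analyte].append(lab.value)
                lab_patients[lab.analyte].add(rec.patient_id)

    labs = {}
    for analyte in Analyte:
        vals = lab_values[analyte]
        n = len(lab_patients[analyte])
        if n == 0:
            labs[analyte] = LabSummary(mean=None, sd=None, n=0)
        else:
            arr = np.asarray(vals)
            sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
            labs[analyte] = LabSummary(mean=float(arr.mean()), sd=sd, n=n)

    return GroupSummary(
        label=label,
        n=len(cohort),
        prescriptions_per_year=tuple(per_year.mean(axis=0)),
        mean_4y_prescriptions=float(totals_4y.mean()),
        median_1y_visits=float(np.median(visits_1y)),
        labs=labs,
    )


@dataclass(frozen=True)
class ConcordanceResult:
    percent: int  # rounded to the nearest integer, as reported
    raw: float


def concordance(flags_a: Sequence[bool], flags_b: Sequence[bool]) -> ConcordanceResult:
    """Percentage of patients for whom the presence/non-presence of a symptom
    agrees between two registrations (e.g. coded vs. free text)."""
    if len(flags_a) != len(flags_b):
        raise DataError(
            f"flag vectors differ in length ({len(flags_a)} vs {len(flags_b)})"
        )
    if len(flags_a) == 0:
        raise DataError("flag vectors must be non-empty")
    a = np.asarray(flags_a, dtype=bool)
    b = np.asarray(flags_b, dtype=bool)
    raw = 100.0 * float(np.mean(a == b))
    return ConcordanceResult(percent=int(round(raw)), raw=raw)
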