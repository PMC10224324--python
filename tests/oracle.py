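"""Independent brute-force scorer used to cross-check the scoring engine.

Reads the shipped rule-set YAML directly with yaml.safe_load and evaluates
every rule with explicit date arithmetic over raw event tuples. Shares no
code with padscreen's RuleSet/scoring path.
"""

from __future__ import annotations

import importlib.resources
from datetime import date, timedelta

import yaml


def load_raw_rules() -> dict:
    path = importlib.resources.files("padscreen").joinpath("data/default_ruleset.yaml")
    return yaml.safe_load(path.read_text(encoding="utf-8"))


def whole_years(birth: date, at: date) -> int:
    y = at.year - birth.year
    if (at.month, at.day) < (birth.month, birth.day):
        y -= 1
    return y


def brute_force_score(record, run_date: date, raw: dict):
    """Score a PatientRecord from first principles.

    Returns (eligible: bool, censoring_date, total: float | None).
    """
    diagnoses = [(e.icpc_code, e.date) for e in record.diagnoses]
    prescriptions = [(e.atc_code, e.date) for e in record.prescriptions]
    labs = [(e.analyte.value, e.value, e.date) for e in record.labs]
    visits = [e.date for e in record.visits]

    # censoring: earliest ambiguous diagnosis on/before the run date
    ambiguous = {entry["code"] for entry in raw["ambiguous"]}
    amb_dates = sorted(d for c, d in diagnoses if c in ambiguous and d <= run_date)
    censor = amb_dates[0] if amb_dates else run_date

    # eligibility: exclusion codes anywhere in the record; age at censoring
    exclusions = {entry["code"] for entry in raw["exclusions"]}
    if any(c in exclusions for c, _ in diagnoses):
        return False, censor, None
    age = whole_years(record.birth_date, censor)
    if age < raw["age_bounds"]["min"] or age > raw["age_bounds"]["max"]:
        return False, censor, None

    total = 0.0

    # antibiotics: per prescription, 4-year window, age >= 6 at prescription
    abx_window = raw["antibiotic_window_years"] * 365
    weights = {r["atc"]: r["weight"] for r in raw["antibiotics"]}
    abx = 0.0
    for code, d in prescriptions:
        if code not in weights:
            continue
        if not (censor - timedelta(days=abx_window) < d <= censor):
            continue
        if whole_years(record.birth_date, d) < raw["antibiotic_min_age_years"]:
            continue
        abx += weights[code]
    end = censor
    if record.enrollment_end is not None and record.enrollment_end < end:
        end = record.enrollment_end
    enrolled = (end - record.enrollment_start).days
    assert enrolled > 0
    if enrolled < abx_window:
        abx = abx * raw["antibiotic_window_years"] / (enrolled / 365)
    total += abx

    # ICPC categories: presence once per rule within the category window
    for cat, rules in raw["icpc_categories"].items():
        years = raw["windows"][cat]["years"]
        for rule in rules:
            hit = False
            for code, d in diagnoses:
                if code not in rule["codes"]:
                    continue
                if d > censor:
                    continue
                if years is not None and d <= censor - timedelta(days=years * 365):
                    continue
                hit = True
            if hit:
                total += rule["weight"]

    # labs: strictly below threshold, any time on/before censoring
    for rule in raw["labs"]:
        if any(
            a == rule["analyte"] and d <= censor and v < rule["threshold"]
            for a, v, d in labs
        ):
            total += rule["weight"]

    # visits: count in the 1-year window
    vr = raw["visits"]
    n = sum(1 for d in visits if censor - timedelta(days=vr["window_days"]) < d <= censor)
    if n >= vr["cutoff"]:
        total += vr["weight"]

    return True, censor, total
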