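import random
from datetime import date, timedelta

import pytest

from padscreen import (
    Analyte,
    DiagnosisEvent,
    LabResult,
    PatientRecord,
    PrescriptionEvent,
    Sex,
    VisitEvent,
    VisitModality,
    default_ruleset,
)

RUN_DATE = date(2021, 11, 18)  # extraction date used throughout the fixtures


@pytest.fixture(scope="session")
def ruleset():
    return default_ruleset()


@pytest.fixture
def run_date():
    return RUN_DATE


def make_record(
    patient_id="p1",
    birth_date=date(1980, 5, 1),
    enrollment_start=date(2000, 1, 1),
    enrollment_end=None,
    diagnoses=(),
    prescriptions=(),
    labs=(),
    visits=(),
):
    """Build a PatientRecord from terse (code/analyte, date[, value]) tuples."""
    return PatientRecord(
        patient_id=patient_id,
        birth_date=birth_date,
        sex=Sex.F,
        enrollment_start=enrollment_start,
        enrollment_end=enrollment_end,
        diagnoses=[DiagnosisEvent(icpc_code=c, date=d) for c, d in diagnoses],
        prescriptions=[PrescriptionEvent(atc_code=c, date=d) for c, d in prescriptions],
        labs=[LabResult(analyte=Analyte(a), value=v, date=d) for a, v, d in labs],
        visits=[
            VisitEvent(date=d, modality=VisitModality.physical) for d in visits
        ],
    )


def random_record(rnd: random.Random, ruleset, patient_id="r1") -> PatientRecord:
    """A random small record (<= 50 events) mixing scored, ambiguous,
    exclusion and unknown codes across a 15-year span before the run date."""
    scored_icpc = sorted(
        {c for rules in ruleset.icpc_categories.values() for r in rules for c in r.codes}
    )
    icpc_pool = (
        scored_icpc
        + sorted(ruleset.ambiguous_codes)
        + sorted(ruleset.exclusion_codes)
        + ["Z99", "A01", "K90.01"]  # codes outside the rule set
    )
    atc_pool = sorted(ruleset.antibiotic_weights) + ["N02BE01", "A02BC01"]
    analytes = list(Analyte)

    def rdate(max_years_back=15):
        return RUN_DATE - timedelta(days=rnd.randint(0, max_years_back * 365))

    birth = RUN_DATE - timedelta(days=rnd.randint(8 * 365, 80 * 365))
    enroll_start = max(birth, RUN_DATE - timedelta(days=rnd.randint(30, 20 * 365)))
    enroll_end = None
    if rnd.random() < 0.2:
        enroll_end = enroll_start + timedelta(
            days=rnd.randint(1, max(2, (RUN_DATE - enroll_start).days))
        )

    def clip(d):
        return max(d, birth)

    diagnoses = [
        DiagnosisEvent(icpc_code=rnd.choice(icpc_pool), date=clip(rdate()))
        for _ in range(rnd.randint(0, 15))
    ]
    prescriptions = [
        PrescriptionEvent(atc_code=rnd.choice(atc_pool), date=clip(rdate(8)))
        for _ in range(rnd.randint(0, 15))
    ]
    labs = [
        LabResult(
            analyte=rnd.choice(analytes),
            value=round(rnd.uniform(0, 40), 2),
            date=clip(rdate()),
        )
        for _ in range(rnd.randint(0, 8))
    ]
    visits = [
        VisitEvent(
            date=clip(rdate(3)),
            modality=rnd.choice([VisitModality.physical, VisitModality.electronic]),
        )
        for _ in range(rnd.randint(0, 12))
    ]
    return PatientRecord(
        patient_id=patient_id,
        birth_date=birth,
        sex=rnd.choice([Sex.F, Sex.M]),
        enrollment_start=enroll_start,
        enrollment_end=enroll_end,
        diagnoses=diagnoses,
        prescriptions=prescriptions,
        labs=labs,
        visits=visits,
    )
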