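"""Synthetic primary-care cohorts with the statistical structure of the
seven study groups.

Each :class:`CohortProfile` describes one patient group — the general GP
population, four confounder groups with overlapping presentations (upper
respiratory tract infections, COPD/asthma, inflammatory bowel disease,
malignancy), and two antibody-deficiency case groups (primary-care coded
immunodeficiency and confirmed PAD). Event streams are simulated as
independent homogeneous Poisson processes within each pre-censoring year;
diagnosis-code presence and lab requests are Bernoulli per code/analyte.

Calibration anchors of the default profiles:

* mean total antibiotic prescriptions in the 4 years before censoring:
  5.14 (PAD, with a linearly rising per-year ramp over years -10..-1, since
  escalation is most pronounced in the final 4 pre-diagnosis years) vs. 0.48
  (general population, flat 0.12/year);
* GP visits: Poisson rates 6.0 (PAD) and 2.0 (general) per year, whose
  1-year count medians are 6 and 2;
* immunoglobulin/calculated-globulin request probabilities of the control
  groups match the observed request sparsity (e.g. ~0.9% of the general
  population with an IgA result), with Gaussian values truncated at zero;
* the two case-group profiles generate *no* immunoglobulin or
  calculated-globulin results: pre-diagnosis, these were never requested.

Case-group records carry a synthetic ``diagnosis_date`` (all their history is
generated before it) so pre-diagnosis censoring can be exercised; controls
are anchored at the run date.
"""

from __future__ import annotations

import json
from datetime import date, timedelta
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .ehr_model import (
    Analyte,
    DiagnosisEvent,
    LabResult,
    PatientRecord,
    PrescriptionEvent,
    Sex,
    VisitEvent,
    VisitModality,
    write_cohort,
)
from .errors import DataError
from .ruleset import RuleSet, default_ruleset

__all__ = [
    "GroupLabel",
    "CohortProfile",
    "SimulationConfig",
    "linear_ramp",
    "default_profiles",
    "generate_cohort",
    "generate_mixed_study",
]

DAYS_PER_YEAR = 365
HISTORY_YEARS = 10


class GroupLabel(str, Enum):
    general = "general"
    upper_rti = "upper_rti"
    copd_asthma = "copd_asthma"
    ibd = "ibd"
    malignancy = "malignancy"
    pc_immunodef = "pc_immunodef"
    pad = "pad"


def linear_ramp(total_last_4_years: float, base_rate: float) -> tuple[float, ...]:
    """Per-year antibiotic rates for years -10..-1 rising linearly from
    *base_rate* (year -10) such that the expected total over the final four
    years equals *total_last_4_years*.

    With rates r_k = base + m*(10-k)/9 for k = 10..1 (k = 1 nearest to the
    censoring date), the last-4-year mass is 4*base + (10/3)*m, so
    m = 3*(total - 4*base)/10.
    """
    if total_last_4_years < 4 * base_rate:
        raise DataError("ramp total is below 4x the base rate")
    m = 3.0 * (total_last_4_years - 4.0 * base_rate) / 10.0
    return tuple(base_rate + m * (10 - k) / 9.0 for k in range(10, 0, -1))


class CohortProfile(BaseModel):
    """Parameters of one synthetic patient group.

    ``antibiotic_rate_per_year`` is either a single flat yearly rate or a
    10-element ramp for years -10..-1 before the censoring anchor (index 0 =
    year -10). ``diagnosis_date_offset_years`` (case groups only) is the
    uniform range, in years before the run date, of the synthetic diagnosis.
    """

    model_config = ConfigDict(extra="forbid")

    label: GroupLabel
    n: int = Field(ge=0)
    age_range: tuple[int, int]
    female_fraction: float = Field(ge=0, le=1)
    antibiotic_rate_per_year: Union[float, tuple[float, ...]]
    visit_rate_per_year: float = Field(ge=0)
    icpc_prevalences: dict[str, float] = Field(default_factory=dict)
    lab_request_probability: dict[Analyte, float] = Field(default_factory=dict)
    lab_value_distribution: dict[Analyte, tuple[float, float]] = Field(
        default_factory=dict
    )
    enrollment_years_distribution: tuple[float, float] = (18.0, 6.0)
    min_enrollment_years: float = Field(default=10.0, ge=0)
    exclusion_code_probability: float = Field(default=0.0, ge=0, le=1)
    ambiguous_code_probability: float = Field(default=0.0, ge=0, le=1)
    diagnosis_date_offset_years: Optional[tuple[float, float]] = None

    @field_validator("age_range")
    @classmethod
    def _age_ordered(cls, v):
        if v[0] > v[1]:
            raise ValueError("age_range must be (min, max) with min <= max")
        return v

    @field_validator("icpc_prevalences", "lab_request_probability")
    @classmethod
    def _probs(cls, v):
        for k, p in v.items():
            if not 0 <= p <= 1:
                raise ValueError(f"probability for {k} out of [0, 1]: {p}")
        return v

    @model_validator(mode="after")
    def _rates(self):
        rates = self.yearly_antibiotic_rates
        if len(rates) != HISTORY_YEARS or any(r < 0 for r in rates):
            raise ValueError("antibiotic rates must be 10 non-negative values")
        if self.diagnosis_date_offset_years is not None:
            lo, hi = self.diagnosis_date_offset_years
            if not 0 <= lo <= hi:
                raise ValueError("diagnosis_date_offset_years must be 0 <= lo <= hi")
        return self

    @property
    def yearly_antibiotic_rates(self) -> tuple[float, ...]:
        r = self.antibiotic_rate_per_year
        if isinstance(r, (int, float)):
            return (float(r),) * HISTORY_YEARS
        return tuple(float(x) for x in r)

    @property
    def is_case_group(self) -> bool:
        return self.diagnosis_date_offset_years is not None

    @property
    def expected_4y_prescriptions(self) -> float:
        return float(sum(self.yearly_antibiotic_rates[-4:]))


class SimulationConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    profiles: list[CohortProfile]
    run_date: date
    seed: int

    @model_validator(mode="after")
    def _unique_labels(self):
        labels = [p.label for p in self.profiles]
        if len(set(labels)) != len(labels):
            raise ValueError("profile labels must be unique")
        return self


# Table-derived value distributions (mean, SD in g/L) for control groups.
_GENERAL_LABS = {
    Analyte.IgA_total: (2.01, 1.06),
    Analyte.IgG1: (3.8, 0.0),
    Analyte.IgG2: (3.34, 0.0),
    Analyte.IgG3: (0.67, 0.0),
    Analyte.IgG4: (0.06, 0.0),
    Analyte.IgG_total: (10.6, 2.87),
    Analyte.IgM_total: (2.63, 4.73),
    Analyte.calculated_globulin: (26.34, 12.12),
}


def default_profiles() -> list[CohortProfile]:
    """The seven default group profiles.

    Group sizes are scaled-down defaults for desk-size simulation (the case
    groups keep their study sizes, 30 and 26; control groups are ~1/30 of the
    study cohorts); every parameter can be overridden per profile.
    """
    return [
        CohortProfile(
            label=GroupLabel.general,
            n=2000,
            age_range=(12, 70),
            female_fraction=0.529,
            antibiotic_rate_per_year=0.12,  # 0.48 expected per 4 years
            visit_rate_per_year=2.0,  # 1-year count median 2
            icpc_prevalences={
                "R74": 0.15,
                "R05": 0.10,
                "A04": 0.08,
                "D11": 0.03,
                "T86": 0.03,
            },
            lab_request_probability={
                Analyte.IgA_total: 0.0093,
                Analyte.IgG_total: 0.0011,
                Analyte.IgM_total: 0.0012,
                Analyte.IgG1: 0.00002,
                Analyte.IgG2: 0.00002,
                Analyte.IgG3: 0.00002,
                Analyte.IgG4: 0.00002,
                Analyte.calculated_globulin: 0.0038,
            },
            lab_value_distribution=_GENERAL_LABS,
            exclusion_code_probability=0.005,
            ambiguous_code_probability=0.002,
        ),
        CohortProfile(
            label=GroupLabel.upper_rti,
            n=450,
            age_range=(12, 65),
            female_fraction=0.574,
            antibiotic_rate_per_year=0.30,
            visit_rate_per_year=3.0,
            icpc_prevalences={"R74": 1.0, "R75": 0.3, "R05": 0.4, "H71": 0.15},
            lab_request_probability={
                Analyte.IgA_total: 0.0183,
                Analyte.IgG_total: 0.0026,
                Analyte.IgM_total: 0.0026,
                Analyte.calculated_globulin: 0.0068,
            },
            lab_value_distribution={
                Analyte.IgA_total: (2.09, 1.11),
                Analyte.IgG_total: (11.28, 2.09),
                Analyte.IgM_total: (1.79, 1.97),
                Analyte.calculated_globulin: (30.66, 9.25),
            },
            exclusion_code_probability=0.005,
            ambiguous_code_probability=0.002,
        ),
        CohortProfile(
            label=GroupLabel.copd_asthma,
            n=150,
            age_range=(15, 70),
            female_fraction=0.532,
            antibiotic_rate_per_year=0.45,
            visit_rate_per_year=3.5,
            icpc_prevalences={"R96": 1.0, "R05": 0.5, "R78": 0.2},
            lab_request_probability={
                Analyte.IgA_total: 0.0142,
                Analyte.IgG_total: 0.0025,
                Analyte.IgM_total: 0.0025,
                Analyte.calculated_globulin: 0.0086,
            },
            lab_value_distribution={
                Analyte.IgA_total: (2.32, 1.44),
                Analyte.IgG_total: (11.08, 1.55),
                Analyte.IgM_total: (2.44, 9.53),
                Analyte.calculated_globulin: (26.79, 13.53),
            },
            exclusion_code_probability=0.005,
            ambiguous_code_probability=0.002,
        ),
        CohortProfile(
            label=GroupLabel.ibd,
            n=50,
            age_range=(18, 70),
            female_fraction=0.546,
            antibiotic_rate_per_year=0.20,
            visit_rate_per_year=3.5,
            icpc_prevalences={
                "D94": 0.7,
                "D94.01": 0.4,
                "D94.02": 0.4,
                "D11": 0.5,
                "D93": 0.3,
            },
            lab_request_probability={
                Analyte.IgA_total: 0.0248,
                Analyte.calculated_globulin: 0.0074,
            },
            lab_value_distribution={
                Analyte.IgA_total: (2.51, 1.00),
                Analyte.calculated_globulin: (33.70, 0.71),
            },
            exclusion_code_probability=0.005,
            ambiguous_code_probability=0.002,
        ),
        CohortProfile(
            label=GroupLabel.malignancy,
            n=60,
            age_range=(35, 70),
            female_fraction=0.605,
            antibiotic_rate_per_year=0.25,
            visit_rate_per_year=4.0,
            # X76 (breast cancer) is outside the rule set: the malignancy
            # control group is defined by having *a* malignancy, not one of
            # the algorithm's scored/ambiguous codes.
            icpc_prevalences={"X76": 0.5, "A04": 0.4, "T08": 0.2},
            lab_request_probability={
                Analyte.IgA_total: 0.0157,
                Analyte.IgG_total: 0.0059,
                Analyte.IgM_total: 0.0066,
                Analyte.calculated_globulin: 0.0151,
            },
            lab_value_distribution={
                Analyte.IgA_total: (2.31, 0.98),
                Analyte.IgG_total: (11.37, 1.96),
                Analyte.IgM_total: (2.49, 6.42),
                Analyte.calculated_globulin: (28.61, 15.83),
            },
            exclusion_code_probability=0.005,
            ambiguous_code_probability=0.01,
        ),
        CohortProfile(
            label=GroupLabel.pc_immunodef,
            n=26,
            age_range=(12, 65),
            female_fraction=0.538,
            antibiotic_rate_per_year=linear_ramp(4.5, 0.3),
            visit_rate_per_year=6.0,
            icpc_prevalences={
                "R74": 0.8,
                "R75": 0.4,
                "R81": 0.30,
                "D11": 0.4,
                "B82": 0.1,
            },
            # Pre-diagnosis, immunoglobulins and calculated globulin were
            # never requested for the case groups.
            lab_request_probability={},
            lab_value_distribution={},
            diagnosis_date_offset_years=(1.0, 8.0),
        ),
        CohortProfile(
            label=GroupLabel.pad,
            n=30,
            age_range=(12, 60),
            female_fraction=0.40,
            antibiotic_rate_per_year=linear_ramp(5.14, 0.3),
            visit_rate_per_year=6.0,  # 1-year count median 6
            # Pre-diagnosis coded-symptom prevalences: upper RTI 100%,
            # gastro-intestinal 57%, pneumonia 37%, bronchiectasis 20%,
            # meningitis 13%, auto-immune spread over common codes.
            icpc_prevalences={
                "R74": 1.0,
                "R75": 0.4,
                "R81": 0.37,
                "R91.02": 0.20,
                "D11": 0.57,
                "N71": 0.13,
                "B82": 0.15,
                "B83.02": 0.12,
                "T86": 0.10,
            },
            lab_request_probability={},
            lab_value_distribution={},
            diagnosis_date_offset_years=(1.0, 8.0),
        ),
    ]


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def generate_cohort(
    profile: CohortProfile,
    run_date: date,
    seed: int,
    ruleset: Optional[RuleSet] = None,
) -> list[PatientRecord]:
    """Generate ``profile.n`` synthetic patient records.

    Output is a pure function of (profile, run_date, seed). Case-group
    records carry ``diagnosis_date``; all their simulated history precedes
    it. Exclusion/ambiguous codes are drawn from *ruleset* (default: the
    shipped rule set).
    """
    if ruleset is None:
        ruleset = default_ruleset()
    rng = _rng(seed)
    atc_codes = sorted(ruleset.antibiotic_weights)
    exclusion_codes = sorted(ruleset.exclusion_codes)
    ambiguous_codes = sorted(ruleset.ambiguous_codes)
    rates = profile.yearly_antibiotic_rates
    records: list[PatientRecord] = []

    for i in range(profile.n):
        if profile.is_case_group:
            lo, hi = profile.diagnosis_date_offset_years
            offset_days = int(rng.uniform(lo * DAYS_PER_YEAR, hi * DAYS_PER_YEAR))
            anchor = run_date - timedelta(days=offset_days)
            diagnosis_date = anchor
        else:
            anchor = run_date
            diagnosis_date = None

        age = float(rng.uniform(profile.age_range[0], profile.age_range[1]))
        birth = anchor - timedelta(days=int(age * 365.25) + 1)
        sex = Sex.F if rng.random() < profile.female_fraction else Sex.M

        mu, sigma = profile.enrollment_years_distribution
        enroll_years = float(np.clip(rng.normal(mu, sigma), profile.min_enrollment_years, age))
        enrollment_start = anchor - timedelta(days=int(enroll_years * DAYS_PER_YEAR))
        if enrollment_start < birth:
            enrollment_start = birth

        prescriptions = []
        for k in range(1, HISTORY_YEARS + 1):  # k = 1 is the year before anchor
            rate = rates[HISTORY_YEARS - k]
            for _ in range(rng.poisson(rate)):
                delta = int((k - 1) * DAYS_PER_YEAR + rng.integers(0, DAYS_PER_YEAR))
                d = anchor - timedelta(days=delta)
                if d >= birth:
                    prescriptions.append(
                        PrescriptionEvent(
                            atc_code=str(rng.choice(atc_codes)), date=d
                        )
                    )

        visits = []
        for k in range(1, HISTORY_YEARS + 1):
            for _ in range(rng.poisson(profile.visit_rate_per_year)):
                delta = int((k - 1) * DAYS_PER_YEAR + rng.integers(0, DAYS_PER_YEAR))
                d = anchor - timedelta(days=delta)
                if d >= birth:
                    visits.append(
                        VisitEvent(
                            date=d,
                            modality=VisitModality.physical
                            if rng.random() < 0.7
                            else VisitModality.electronic,
                        )
                    )

        diagnoses = []
        for code, p in profile.icpc_prevalences.items():
            if rng.random() < p:
                d = anchor - timedelta(days=int(rng.integers(0, HISTORY_YEARS * DAYS_PER_YEAR)))
                if d >= birth:
                    diagnoses.append(DiagnosisEvent(icpc_code=code, date=d))
        if profile.exclusion_code_probability and rng.random() < profile.exclusion_code_probability:
            code = str(rng.choice(exclusion_codes))
            d = anchor - timedelta(days=int(rng.integers(0, HISTORY_YEARS * DAYS_PER_YEAR)))
            if d >= birth:
                diagnoses.append(DiagnosisEvent(icpc_code=code, date=d))
        if profile.ambiguous_code_probability and rng.random() < profile.ambiguous_code_probability:
            code = str(rng.choice(ambiguous_codes))
            d = anchor - timedelta(days=int(rng.integers(0, HISTORY_YEARS * DAYS_PER_YEAR)))
            if d >= birth:
                diagnoses.append(DiagnosisEvent(icpc_code=code, date=d))

        labs = []
        for analyte, p in profile.lab_request_probability.items():
            if rng.random() < p:
                mean, sd = profile.lab_value_distribution.get(analyte, (0.0, 0.0))
                value = max(0.0, float(rng.normal(mean, sd)))
                d = anchor - timedelta(days=int(rng.integers(0, HISTORY_YEARS * DAYS_PER_YEAR)))
                if d >= birth:
                    labs.append(LabResult(analyte=analyte, value=value, date=d))

        records.append(
            PatientRecord(
                patient_id=f"{profile.label.value}-{i + 1:05d}",
                birth_date=birth,
                sex=sex,
                enrollment_start=enrollment_start,
                enrollment_end=None,
                diagnoses=diagnoses,
                prescriptions=prescriptions,
                labs=labs,
                visits=visits,
                diagnosis_date=diagnosis_date,
            )
        )
    return records


def generate_mixed_study(
    config: SimulationConfig,
    out_dir,
    ruleset: Optional[RuleSet] = None,
) -> Path:
    """Generate every profile in *config*, write one cohort-table directory
    per group and a manifest sufficient for exact regeneration.

    Per-group seeds are ``config.seed + group index``. Returns the manifest
    path. The manifest records the seed, run date, full profile parameters
    and, for case groups, each patient's synthetic diagnosis date.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "seed": config.seed,
        "run_date": config.run_date.isoformat(),
        "groups": {},
    }
    for idx, profile in enumerate(config.profiles):
        records = generate_cohort(
            profile, config.run_date, config.seed + idx, ruleset=ruleset
        )
        group_dir = out_dir / profile.label.value
        write_cohort(records, group_dir)
        entry = {
            "n": profile.n,
            "seed": config.seed + idx,
            "profile": json.loads(profile.model_dump_json()),
        }
        if profile.is_case_group:
            entry["diagnosis_dates"] = {
                r.patient_id: r.diagnosis_date.isoformat() for r in records
            }
        manifest["groups"][profile.label.value] = entry
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2), encoding="utf-8")
    return manifest_path
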