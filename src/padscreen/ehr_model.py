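"""Domain types for structured primary-care EHR data and cohort-table I/O.

A cohort lives in five comma-separated UTF-8 tables with header rows:

====================  =========================================================
table                 columns
====================  =========================================================
``patients``          patient_id, birth_date, sex, enrollment_start,
                      enrollment_end (empty = still enrolled)
``diagnoses``         patient_id, icpc_code, date
``prescriptions``     patient_id, atc_code, date
``labs``              patient_id, analyte, value_g_per_l, date
``visits``            patient_id, date, modality
====================  =========================================================

Dates are ISO-8601 calendar dates (no time of day: GP records operate at date
granularity). ICPC codes look like ``R81`` or ``R75.01`` (letter, two digits,
optional two-digit sub-code); ATC codes are 7-character level-5 codes such as
``J01CA04``. Lab values are concentrations in g/L.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from datetime import date
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .errors import DataError, SchemaError

__all__ = [
    "Sex",
    "Analyte",
    "VisitModality",
    "DiagnosisEvent",
    "PrescriptionEvent",
    "LabResult",
    "VisitEvent",
    "PatientRecord",
    "normalize_icpc",
    "normalize_atc",
    "age_in_years",
    "compute_calculated_globulin",
    "load_cohort",
    "write_cohort",
    "write_results",
    "RESULT_COLUMNS",
]

ICPC_PATTERN = re.compile(r"^[A-Z]\d{2}(\.\d{2})?$")
ATC_PATTERN = re.compile(r"^[A-Z]\d{2}[A-Z]{2}\d{2}$")


class Sex(str, Enum):
    F = "F"
    M = "M"
    unknown = "unknown"


class Analyte(str, Enum):
    IgG_total = "IgG_total"
    IgG1 = "IgG1"
    IgG2 = "IgG2"
    IgG3 = "IgG3"
    IgG4 = "IgG4"
    IgM_total = "IgM_total"
    IgA_total = "IgA_total"
    calculated_globulin = "calculated_globulin"
    total_protein = "total_protein"
    albumin = "albumin"


class VisitModality(str, Enum):
    physical = "physical"
    electronic = "electronic"


def normalize_icpc(code: str) -> str:
    """Normalize an ICPC code: trim whitespace, uppercase. Idempotent."""
    return str(code).strip().upper()


def normalize_atc(code: str) -> str:
    """Normalize an ATC code: trim whitespace, uppercase. Idempotent."""
    return str(code).strip().upper()


def age_in_years(birth_date: date, at: date) -> int:
    """Whole years elapsed since *birth_date* at date *at* (birthday convention)."""
    years = at.year - birth_date.year
    if (at.month, at.day) < (birth_date.month, birth_date.day):
        years -= 1
    return years


@dataclass(frozen=True)
class DiagnosisEvent:
    icpc_code: str
    date: date

    def __post_init__(self) -> None:
        if not ICPC_PATTERN.match(self.icpc_code):
            raise DataError(f"invalid ICPC code {self.icpc_code!r}")


@dataclass(frozen=True)
class PrescriptionEvent:
    atc_code: str
    date: date

    def __post_init__(self) -> None:
        if not ATC_PATTERN.match(self.atc_code):
            raise DataError(f"invalid ATC level-5 code {self.atc_code!r}")


@dataclass(frozen=True)
class LabResult:
    analyte: Analyte
    value: float  # g/L
    date: date

    def __post_init__(self) -> None:
        if self.value < 0:
            raise DataError(
                f"negative lab value {self.value} for {self.analyte.value}"
            )


@dataclass(frozen=True)
class VisitEvent:
    date: date
    modality: VisitModality


@dataclass
class PatientRecord:
    """One patient's full structured primary-care record.

    Event streams are kept sorted ascending by date. ``diagnosis_date`` is
    optional metadata used by synthetic case cohorts so that screening can be
    censored at the (synthetic) diagnosis; it is not part of the cohort
    tables.
    """

    patient_id: str
    birth_date: date
    sex: Sex = Sex.unknown
    enrollment_start: date = None  # type: ignore[assignment]
    enrollment_end: Optional[date] = None  # None = still enrolled
    diagnoses: list[DiagnosisEvent] = field(default_factory=list)
    prescriptions: list[PrescriptionEvent] = field(default_factory=list)
    labs: list[LabResult] = field(default_factory=list)
    visits: list[VisitEvent] = field(default_factory=list)
    diagnosis_date: Optional[date] = None

    def __post_init__(self) -> None:
        if self.enrollment_start is None:
            self.enrollment_start = self.birth_date
        if self.enrollment_end is not None and self.enrollment_start > self.enrollment_end:
            raise DataError(
                f"patient {self.patient_id}: enrollment_start after enrollment_end"
            )
        self.sort_events()
        for ev in self.all_events():
            if ev.date < self.birth_date:
                raise DataError(
                    f"patient {self.patient_id}: event on {ev.date} precedes birth"
                )

    def sort_events(self) -> None:
        self.diagnoses.sort(key=lambda e: e.date)
        self.prescriptions.sort(key=lambda e: e.date)
        self.labs.sort(key=lambda e: e.date)
        self.visits.sort(key=lambda e: e.date)

    def all_events(self):
        yield from self.diagnoses
        yield from self.prescriptions
        yield from self.labs
        yield from self.visits

    def age_at(self, at: date) -> int:
        return age_in_years(self.birth_date, at)

    def truncated(self, cutoff: date) -> "PatientRecord":
        """A copy keeping only events dated on or before *cutoff*."""
        return replace(
            self,
            diagnoses=[e for e in self.diagnoses if e.date <= cutoff],
            prescriptions=[e for e in self.prescriptions if e.date <= cutoff],
            labs=[e for e in self.labs if e.date <= cutoff],
            visits=[e for e in self.visits if e.date <= cutoff],
        )


def compute_calculated_globulin(total_protein: float, albumin: float) -> float:
    """Calculated globulin in g/L: total protein minus albumin.

    An inexpensive proxy for hypogammaglobulinemia when immunoglobulins were
    never requested. A negative result is physiologically impossible and
    triggers a data-quality warning, but the value is still returned so the
    caller can inspect it.
    """
    if total_protein < 0 or albumin < 0:
        raise DataError("total protein and albumin must be non-negative")
    globulin = total_protein - albumin
    if globulin < 0:
        warnings.warn(
            f"calculated globulin {globulin:g} g/L is negative "
            f"(albumin {albumin:g} > total protein {total_protein:g})",
            stacklevel=2,
        )
    return globulin


# ---------------------------------------------------------------------------
# Table I/O

TABLE_COLUMNS = {
    "patients": ["patient_id", "birth_date", "sex", "enrollment_start", "enrollment_end"],
    "diagnoses": ["patient_id", "icpc_code", "date"],
    "prescriptions": ["patient_id", "atc_code", "date"],
    "labs": ["patient_id", "analyte", "value_g_per_l", "date"],
    "visits": ["patient_id", "date", "modality"],
}

RESULT_COLUMNS = [
    "patient_id",
    "censoring_date",
    "eligible",
    "exclusion_reason",
    "antibiotic_score",
    "respiratory_tract_infections_score",
    "gastro_intestinal_score",
    "other_infections_score",
    "auto_immune_score",
    "malignancy_lymphoproliferative_other_score",
    "lab_score",
    "visit_score",
    "total_score",
]

# Telephone consultations count the same as any other contact in the
# algorithm, so they are folded into "electronic" at load time.
_MODALITY_ALIASES = {"telephone": VisitModality.electronic, "phone": VisitModality.electronic}


def _read_table(name: str, path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in TABLE_COLUMNS[name] if c not in df.columns]
    if missing:
        raise SchemaError(f"table {name!r} ({path}): missing column(s) {missing}")
    return df


def _parse_date(name: str, path, row_idx: int, value: str, *, required: bool = True):
    value = value.strip()
    if value == "":
        if required:
            raise DataError(f"table {name!r} ({path}) row {row_idx + 2}: empty date")
        return None
    try:
        return date.fromisoformat(value)
    except ValueError as exc:
        raise DataError(
            f"table {name!r} ({path}) row {row_idx + 2}: unparseable date {value!r}"
        ) from exc


def load_cohort(paths: Mapping[str, object]) -> list[PatientRecord]:
    """Load a cohort from the five delimited-text tables.

    *paths* maps the table names ``patients``, ``diagnoses``, ``prescriptions``,
    ``labs``, ``visits`` to file paths. Codes are normalized (trimmed,
    uppercased), event streams attached to their patients and sorted by date.
    When a total-protein and an albumin result share a date, a
    ``calculated_globulin`` result is derived and appended for that date.

    Raises :class:`SchemaError` for missing tables/columns, :class:`DataError`
    for unparseable rows or event rows whose patient_id has no patients-table
    row.
    """
    missing_tables = [t for t in TABLE_COLUMNS if t not in paths]
    if missing_tables:
        raise SchemaError(f"missing table path(s): {missing_tables}")

    tables = {name: _read_table(name, paths[name]) for name in TABLE_COLUMNS}

    records: dict[str, PatientRecord] = {}
    for i, row in tables["patients"].iterrows():
        pid = row["patient_id"].strip()
        if pid in records:
            raise DataError(f"duplicate patient_id {pid!r} in patients table")
        sex_raw = row["sex"].strip()
        try:
            sex = Sex(sex_raw) if sex_raw else Sex.unknown
        except ValueError as exc:
            raise DataError(f"patients table row {i + 2}: unknown sex {sex_raw!r}") from exc
        records[pid] = PatientRecord(
            patient_id=pid,
            birth_date=_parse_date("patients", paths["patients"], i, row["birth_date"]),
            sex=sex,
            enrollment_start=_parse_date(
                "patients", paths["patients"], i, row["enrollment_start"]
            ),
            enrollment_end=_parse_date(
                "patients", paths["patients"], i, row["enrollment_end"], required=False
            ),
        )

    def _patient(name: str, pid: str, orphans: set) -> Optional[PatientRecord]:
        pid = pid.strip()
        rec = records.get(pid)
        if rec is None:
            orphans.add(pid)
        return rec

    orphans: set[str] = set()
    for i, row in tables["diagnoses"].iterrows():
        rec = _patient("diagnoses", row["patient_id"], orphans)
        if rec is None:
            continue
        rec.diagnoses.append(
            DiagnosisEvent(
                icpc_code=normalize_icpc(row["icpc_code"]),
                date=_parse_date("diagnoses", paths["diagnoses"], i, row["date"]),
            )
        )
    for i, row in tables["prescriptions"].iterrows():
        rec = _patient("prescriptions", row["patient_id"], orphans)
        if rec is None:
            continue
        rec.prescriptions.append(
            PrescriptionEvent(
                atc_code=normalize_atc(row["atc_code"]),
                date=_parse_date("prescriptions", paths["prescriptions"], i, row["date"]),
            )
        )
    for i, row in tables["labs"].iterrows():
        rec = _patient("labs", row["patient_id"], orphans)
        if rec is None:
            continue
        analyte_raw = row["analyte"].strip()
        try:
            analyte = Analyte(analyte_raw)
        except ValueError as exc:
            raise DataError(
                f"labs table row {i + 2}: unknown analyte {analyte_raw!r}"
            ) from exc
        try:
            value = float(row["value_g_per_l"])
        except ValueError as exc:
            raise DataError(
                f"labs table row {i + 2}: unparseable value {row['value_g_per_l']!r}"
            ) from exc
        rec.labs.append(
            LabResult(
                analyte=analyte,
                value=value,
                date=_parse_date("labs", paths["labs"], i, row["date"]),
            )
        )
    for i, row in tables["visits"].iterrows():
        rec = _patient("visits", row["patient_id"], orphans)
        if rec is None:
            continue
        modality_raw = row["modality"].strip().lower()
        modality = _MODALITY_ALIASES.get(modality_raw)
        if modality is None:
            try:
                modality = VisitModality(modality_raw)
            except ValueError as exc:
                raise DataError(
                    f"visits table row {i + 2}: unknown modality {modality_raw!r}"
                ) from exc
        rec.visits.append(
            VisitEvent(
                date=_parse_date("visits", paths["visits"], i, row["date"]),
                modality=modality,
            )
        )

    if orphans:
        raise DataError(
            "event rows reference patient_id(s) absent from the patients table: "
            + ", ".join(sorted(orphans))
        )

    for rec in records.values():
        _derive_calculated_globulin(rec)
        rec.sort_events()
        for ev in rec.all_events():
            if ev.date < rec.birth_date:
                raise DataError(
                    f"patient {rec.patient_id}: event on {ev.date} precedes birth"
                )
    return list(records.values())


def _derive_calculated_globulin(rec: PatientRecord) -> None:
    """Append calculated-globulin results where total protein and albumin
    were measured on the same date and no stored result exists for it."""
    existing = {lab.date for lab in rec.labs if lab.analyte is Analyte.calculated_globulin}
    tp = {lab.date: lab.value for lab in rec.labs if lab.analyte is Analyte.total_protein}
    alb = {lab.date: lab.value for lab in rec.labs if lab.analyte is Analyte.albumin}
    for d in sorted(tp.keys() & alb.keys() - existing):
        rec.labs.append(
            LabResult(
                analyte=Analyte.calculated_globulin,
                value=compute_calculated_globulin(tp[d], alb[d]),
                date=d,
            )
        )


def write_cohort(records: Iterable[PatientRecord], out_dir) -> dict[str, Path]:
    """Write records back to the five cohort tables under *out_dir*.

    Returns the mapping of table name → path, re-loadable by
    :func:`load_cohort` (round trip reproduces identical records, minus any
    ``diagnosis_date`` metadata, which travels in simulation manifests
    instead).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows: dict[str, list] = {name: [] for name in TABLE_COLUMNS}
    for rec in records:
        rows["patients"].append(
            {
                "patient_id": rec.patient_id,
                "birth_date": rec.birth_date.isoformat(),
                "sex": rec.sex.value,
                "enrollment_start": rec.enrollment_start.isoformat(),
                "enrollment_end": "" if rec.enrollment_end is None else rec.enrollment_end.isoformat(),
            }
        )
        for e in rec.diagnoses:
            rows["diagnoses"].append(
                {"patient_id": rec.patient_id, "icpc_code": e.icpc_code, "date": e.date.isoformat()}
            )
        for e in rec.prescriptions:
            rows["prescriptions"].append(
                {"patient_id": rec.patient_id, "atc_code": e.atc_code, "date": e.date.isoformat()}
            )
        for e in rec.labs:
            rows["labs"].append(
                {
                    "patient_id": rec.patient_id,
                    "analyte": e.analyte.value,
                    "value_g_per_l": repr(e.value),
                    "date": e.date.isoformat(),
                }
            )
        for e in rec.visits:
            rows["visits"].append(
                {"patient_id": rec.patient_id, "date": e.date.isoformat(), "modality": e.modality.value}
            )
    paths = {}
    for name, cols in TABLE_COLUMNS.items():
        path = out_dir / f"{name}.csv"
        pd.DataFrame(rows[name], columns=cols).to_csv(path, index=False)
        paths[name] = path
    return paths


def write_results(results: Sequence, path) -> None:
    """Write screening results as a delimited-text table, one row per patient.

    Column order is fixed (:data:`RESULT_COLUMNS`). Ineligible patients have
    empty score cells and a populated ``exclusion_reason``.
    """
    rows = []
    for res in results:
        rows.append(res.as_row())
    pd.DataFrame(rows, columns=RESULT_COLUMNS).to_csv(path, index=False)
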