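"""Machine-readable representation of the PAD screening algorithm.

The algorithm is a weighted rule set over coded primary-care events:
antibiotic prescriptions (ATC codes, scored per prescription in a 4-year
window with enrollment-time normalization), diagnostic ICPC codes in five
clinical categories (scored once on presence, within a 10-year or lifetime
look-back), reduced immunoglobulin / calculated-globulin laboratory values,
and a GP-visit frequency criterion. Ambiguous diagnoses truncate the
screening window; exclusion diagnoses and age bounds remove patients from
screening altogether.

The published default ships as ``data/default_ruleset.yaml``; alternative
rule sets load from YAML or JSON files with the same schema.
"""

from __future__ import annotations

import importlib.resources
import json
from enum import Enum
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .ehr_model import Analyte, normalize_atc, normalize_icpc
from .errors import RuleSetError

__all__ = [
    "Category",
    "AntibioticRule",
    "IcpcRule",
    "LabRule",
    "VisitRule",
    "AmbiguousCode",
    "ExclusionCode",
    "RuleSet",
    "default_ruleset",
    "load_ruleset",
    "dump_ruleset",
    "component_count",
]


class Category(str, Enum):
    respiratory_tract_infections = "respiratory_tract_infections"
    gastro_intestinal = "gastro_intestinal"
    other_infections = "other_infections"
    auto_immune = "auto_immune"
    malignancy_lymphoproliferative_other = "malignancy_lymphoproliferative_other"


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)


class AntibioticRule(_StrictModel):
    """Score *weight* points for every prescription of this ATC code."""

    atc: str
    description: str = ""
    weight: float = Field(gt=0)

    @field_validator("atc")
    @classmethod
    def _norm(cls, v: str) -> str:
        return normalize_atc(v)

    @property
    def component_id(self) -> str:
        return f"abx:{self.atc}"


class IcpcRule(_StrictModel):
    """Score *weight* points once if any of *codes* is present in the window.

    Nearly all rules carry a single code; a rule may list several codes that
    denote the same condition (the published table lists Hodgkin's disease
    under both its parent code and its sub-code with identical weight).
    """

    codes: tuple[str, ...] = Field(min_length=1)
    description: str = ""
    weight: float = Field(gt=0)

    @field_validator("codes")
    @classmethod
    def _norm(cls, v) -> tuple[str, ...]:
        return tuple(normalize_icpc(c) for c in v)

    @property
    def component_id(self) -> str:
        return "icpc:" + "+".join(self.codes)


class LabRule(_StrictModel):
    """Score *weight* points if any result for *analyte* is strictly below
    *threshold* (g/L). A value exactly at the threshold does not score."""

    analyte: Analyte
    threshold: float = Field(gt=0)
    weight: float = Field(gt=0)

    @property
    def component_id(self) -> str:
        return f"lab:{self.analyte.value}"


class VisitRule(_StrictModel):
    """Score *weight* points if the patient had at least *cutoff* GP contacts
    (physical or electronic) in the *window_days* before the censoring date."""

    cutoff: int = Field(default=6, ge=1)
    window_days: int = Field(default=365, ge=1)
    weight: float = Field(default=3, gt=0)

    @property
    def component_id(self) -> str:
        return "visits"


class CodeEntry(_StrictModel):
    code: str
    description: str = ""

    @field_validator("code")
    @classmethod
    def _norm(cls, v: str) -> str:
        return normalize_icpc(v)


AmbiguousCode = CodeEntry
ExclusionCode = CodeEntry


class _Window(_StrictModel):
    years: Optional[int] = Field(default=None, ge=1)  # None = lifetime


class _AgeBounds(_StrictModel):
    min: int = Field(ge=0)
    max: int = Field(ge=0)

    @model_validator(mode="after")
    def _ordered(self):
        if self.min > self.max:
            raise ValueError("age_bounds.min exceeds age_bounds.max")
        return self


class RuleSet(_StrictModel):
    """The complete screening algorithm."""

    antibiotics: tuple[AntibioticRule, ...]
    icpc_categories: dict[Category, tuple[IcpcRule, ...]]
    labs: tuple[LabRule, ...]
    visits: VisitRule = VisitRule()
    windows: dict[Category, _Window]
    antibiotic_window_years: int = Field(default=4, ge=1)
    antibiotic_min_age_years: int = Field(default=6, ge=0)
    ambiguous: tuple[AmbiguousCode, ...] = ()
    exclusions: tuple[ExclusionCode, ...] = ()
    age_bounds: _AgeBounds = _AgeBounds(min=12, max=70)

    @model_validator(mode="after")
    def _consistent(self):
        atcs = [r.atc for r in self.antibiotics]
        if len(set(atcs)) != len(atcs):
            raise ValueError("duplicate ATC code in antibiotic rules")
        seen: set[tuple[str, Category]] = set()
        for cat, rules in self.icpc_categories.items():
            for rule in rules:
                for code in rule.codes:
                    key = (code, cat)
                    if key in seen:
                        raise ValueError(f"duplicate ICPC rule for {code} in {cat.value}")
                    seen.add(key)
        analytes = [r.analyte for r in self.labs]
        if len(set(analytes)) != len(analytes):
            raise ValueError("duplicate analyte in lab rules")
        amb = {e.code for e in self.ambiguous}
        exc = {e.code for e in self.exclusions}
        overlap = amb & exc
        if overlap:
            raise ValueError(
                f"codes listed as both ambiguous and exclusion: {sorted(overlap)}"
            )
        scored = {code for code, _ in seen}
        scored_excluded = scored & exc
        if scored_excluded:
            raise ValueError(
                f"scored ICPC codes appear in exclusions: {sorted(scored_excluded)}"
            )
        missing = set(self.icpc_categories) - set(self.windows)
        if missing:
            raise ValueError(
                f"no look-back window for categories: {sorted(c.value for c in missing)}"
            )
        return self

    # -- lookups used by the scoring engine ---------------------------------

    @property
    def antibiotic_weights(self) -> dict[str, float]:
        return {r.atc: r.weight for r in self.antibiotics}

    @property
    def ambiguous_codes(self) -> frozenset[str]:
        return frozenset(e.code for e in self.ambiguous)

    @property
    def exclusion_codes(self) -> frozenset[str]:
        return frozenset(e.code for e in self.exclusions)

    def window_days(self, category: Category) -> Optional[int]:
        """Look-back length in days for a category (365 days/year), or None
        for a lifetime window."""
        years = self.windows[category].years
        return None if years is None else years * 365

    def iter_components(self):
        """Yield (component_id, rule) for every distinct scored component."""
        for r in self.antibiotics:
            yield r.component_id, r
        for rules in self.icpc_categories.values():
            for r in rules:
                yield r.component_id, r
        for r in self.labs:
            yield r.component_id, r
        yield self.visits.component_id, self.visits

    def find_component(self, component_id: str):
        for cid, rule in self.iter_components():
            if cid == component_id:
                return rule
        raise RuleSetError(f"unknown component {component_id!r}")

    def icpc_rule_category(self, rule: IcpcRule) -> Category:
        for cat, rules in self.icpc_categories.items():
            if rule in rules:
                return cat
        raise RuleSetError(f"rule {rule.component_id} not in this rule set")


def component_count(ruleset: RuleSet) -> int:
    """Number of distinct scored components (each multi-code ICPC rule counts
    once). The published default has 106."""
    return sum(1 for _ in ruleset.iter_components())


def _default_path():
    return importlib.resources.files("padscreen").joinpath("data/default_ruleset.yaml")


def default_ruleset() -> RuleSet:
    """The published algorithm, loaded from the packaged YAML file."""
    with importlib.resources.as_file(_default_path()) as p:
        return load_ruleset(p)


def load_ruleset(path) -> RuleSet:
    """Load and validate a rule set from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    try:
        raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise RuleSetError(f"cannot parse rule-set file {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise RuleSetError(f"rule-set file {path} must contain a mapping")
    try:
        return RuleSet.model_validate(raw)
    except Exception as exc:  # pydantic.ValidationError
        raise RuleSetError(f"invalid rule set in {path}: {exc}") from exc


def dump_ruleset(ruleset: RuleSet, path) -> None:
    """Serialize a rule set to YAML or JSON (by file extension)."""
    path = Path(path)
    data = ruleset.model_dump(mode="json")
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2), encoding="utf-8")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False), encoding="utf-8")
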