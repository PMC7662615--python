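"""Cohort schema, validation and CSV I/O.

A cohort is an ordered collection of worker records, each carrying the three
categorical predictors studied (gender, age, family history of hearing
problems) and at least one representation of the outcome: a raw per-ear
audiogram, a binaural-loss percentage, or the discretized loss group.

Loss groups are labelled ``"1"``–``"5"`` internally; Roman numerals
(``"I"``–``"V"``) and ``"Group 1"``–``"Group 5"`` are accepted on input and
Roman numerals are written to CSV, since published tables use both notations
for the same five states.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

from .audiometry import (
    AUDIOMETRY_FREQS_HZ,
    Audiogram,
    binaural_loss_from_audiogram,
    discretize_age,
    discretize_binaural_loss,
)

GENDER_STATES = ("Women", "Men")
AGE_GROUP_STATES = ("<29", "29-34", "35-39", "40-48", ">=49")
FAMILY_HISTORY_STATES = ("No", "Yes")
LOSS_GROUP_STATES = ("1", "2", "3", "4", "5")

_ROMAN = {"1": "I", "2": "II", "3": "III", "4": "IV", "5": "V"}
_FROM_ROMAN = {v: k for k, v in _ROMAN.items()}


def canonical_loss_group(label: str) -> str:
    """Map any accepted loss-group notation onto the canonical labels 1-5."""
    s = str(label).strip()
    if s in LOSS_GROUP_STATES:
        return s
    if s.upper() in _FROM_ROMAN:
        return _FROM_ROMAN[s.upper()]
    if s.lower().startswith("group"):
        tail = s[5:].strip()
        if tail in LOSS_GROUP_STATES:
            return tail
    raise ValueError(f"unknown loss-group label: {label!r}")


def loss_group_roman(label: str) -> str:
    return _ROMAN[canonical_loss_group(label)]


class CohortError(Exception):
    """Raised for schema-level or row-level CSV problems."""


@dataclass(frozen=True)
class VariableSpec:
    """A discrete study variable: its name and ordered category labels."""

    name: str
    states: tuple[str, ...]
    ordinal: bool = False

    def __post_init__(self) -> None:
        if len(self.states) < 2:
            raise ValueError(f"{self.name}: a discrete variable needs >=2 states")
        if len(set(self.states)) != len(self.states):
            raise ValueError(f"{self.name}: duplicate state labels")

    @property
    def cardinality(self) -> int:
        return len(self.states)

    def index(self, state: str) -> int:
        try:
            return self.states.index(state)
        except ValueError:
            raise ValueError(
                f"{self.name}: state {state!r} not in {self.states}"
            ) from None


def canonical_schema() -> dict[str, VariableSpec]:
    """The four study variables in their canonical state order."""
    return {
        "gender": VariableSpec("gender", GENDER_STATES),
        "age_group": VariableSpec("age_group", AGE_GROUP_STATES, ordinal=True),
        "family_history": VariableSpec("family_history", FAMILY_HISTORY_STATES),
        "loss_group": VariableSpec("loss_group", LOSS_GROUP_STATES, ordinal=True),
    }


@dataclass
class WorkerRecord:
    """One subject: categorical predictors plus some representation of loss."""

    id: str
    gender: str
    age_years: int
    family_history: str
    audiogram: Optional[Audiogram] = None
    binaural_loss_pct: Optional[float] = None
    loss_group: Optional[str] = None

    @property
    def age_group(self) -> str:
        return AGE_GROUP_STATES[discretize_age(self.age_years) - 1]

    def resolved_loss_group(self) -> str:
        """Loss group, computing it from the percentage or audiogram if absent."""
        if self.loss_group is not None:
            return self.loss_group
        pct = self.binaural_loss_pct
        if pct is None and self.audiogram is not None:
            pct = binaural_loss_from_audiogram(self.audiogram).binaural
        if pct is None:
            raise ValueError(f"record {self.id}: no loss information")
        return str(discretize_binaural_loss(pct))


@dataclass
class Violation:
    record_id: str
    message: str


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def to_json(self) -> str:
        return json.dumps(
            {
                "ok": self.ok,
                "violations": [
                    {"record_id": v.record_id, "message": v.message}
                    for v in self.violations
                ],
            },
            indent=2,
        )


@dataclass
class Cohort:
    records: list[WorkerRecord]
    schema: dict[str, VariableSpec] = field(default_factory=canonical_schema)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[WorkerRecord]:
        return iter(self.records)

    def to_dataframe(self):
        """Discretized view: one row per record, categorical columns only."""
        import pandas as pd

        return pd.DataFrame(
            {
                "id": [r.id for r in self.records],
                "gender": [r.gender for r in self.records],
                "age_group": [r.age_group for r in self.records],
                "family_history": [r.family_history for r in self.records],
                "loss_group": [r.resolved_loss_group() for r in self.records],
            }
        )


_EAR_COLUMNS = [f"{side}{f}" for side in "lr" for f in AUDIOMETRY_FREQS_HZ]
_MANDATORY = ("id", "gender", "age_years", "family_history")
_OPTIONAL = ("binaural_loss_pct", "loss_group", *_EAR_COLUMNS)
CSV_COLUMNS = (*_MANDATORY, *_OPTIONAL)


def _parse_row(row: dict[str, str], line_no: int) -> WorkerRecord:
    def fail(msg: str) -> CohortError:
        return CohortError(f"row {line_no}: {msg}")

    gender = row["gender"].strip()
    if gender not in GENDER_STATES:
        raise fail(f"gender {row['gender']!r} not one of {GENDER_STATES}")
    fh = row["family_history"].strip()
    if fh not in FAMILY_HISTORY_STATES:
        raise fail(f"family_history {row['family_history']!r} not one of {FAMILY_HISTORY_STATES}")
    try:
        age = int(row["age_years"])
    except ValueError:
        raise fail(f"non-integer age_years {row['age_years']!r}") from None

    audiogram = None
    ear_vals = [row.get(c, "").strip() for c in _EAR_COLUMNS]
    if any(ear_vals):
        if not all(ear_vals):
            raise fail("incomplete audiogram: all 8 threshold columns required")
        try:
            thresholds = [float(v) for v in ear_vals]
        except ValueError:
            raise fail("non-numeric audiometric threshold") from None
        audiogram = Audiogram(tuple(thresholds[:4]), tuple(thresholds[4:]))

    pct_raw = row.get("binaural_loss_pct", "").strip()
    pct = None
    if pct_raw:
        try:
            pct = float(pct_raw)
        except ValueError:
            raise fail(f"non-numeric binaural_loss_pct {pct_raw!r}") from None

    group_raw = row.get("loss_group", "").strip()
    group = None
    if group_raw:
        try:
            group = canonical_loss_group(group_raw)
        except ValueError as exc:
            raise fail(str(exc)) from None

    if audiogram is None and pct is None and group is None:
        raise fail("record carries no loss information (audiogram, percentage or group)")
    return WorkerRecord(
        id=row["id"].strip(),
        gender=gender,
        age_years=age,
        family_history=fh,
        audiogram=audiogram,
        binaural_loss_pct=pct,
        loss_group=group,
    )


def read_cohort_csv(path, schema: Optional[dict[str, VariableSpec]] = None) -> Cohort:
    """Read a cohort from CSV; parse failures name the offending row.

    Row numbers count data rows, the header being row 0.
    """
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise CohortError(f"{path}: empty file (no header row)")
        missing = [c for c in _MANDATORY if c not in reader.fieldnames]
        if missing:
            raise CohortError(f"{path}: missing mandatory column(s) {missing}")
        records = [_parse_row(row, i) for i, row in enumerate(reader, start=1)]
    return Cohort(records, schema or canonical_schema())


def write_cohort_csv(cohort: Cohort, path) -> None:
    """Write a cohort to CSV; inverse of :func:`read_cohort_csv`.

    Percentages are written with ``repr`` so the round trip is exact;
    loss groups are written as Roman numerals.
    """
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for r in cohort:
            ears = [""] * 8
            if r.audiogram is not None:
                ears = [repr(t) for t in (*r.audiogram.left, *r.audiogram.right)]
            writer.writerow(
                [
                    r.id,
                    r.gender,
                    r.age_years,
                    r.family_history,
                    "" if r.binaural_loss_pct is None else repr(r.binaural_loss_pct),
                    "" if r.loss_group is None else loss_group_roman(r.loss_group),
                    *ears,
                ]
            )


def validate_cohort(cohort: Cohort) -> ValidationReport:
    """Check every record invariant; violations are data, not exceptions."""
    report = ValidationReport()
    seen: set[str] = set()
    for r in cohort:
        if r.id in seen:
            report.violations.append(Violation(r.id, "duplicate record id"))
        seen.add(r.id)
        if r.gender not in GENDER_STATES:
            report.violations.append(Violation(r.id, f"invalid gender {r.gender!r}"))
        if r.family_history not in FAMILY_HISTORY_STATES:
            report.violations.append(
                Violation(r.id, f"invalid family_history {r.family_history!r}")
            )
        if r.age_years < 0:
            report.violations.append(Violation(r.id, f"negative age {r.age_years}"))
        if r.audiogram is None and r.binaural_loss_pct is None and r.loss_group is None:
            report.violations.append(Violation(r.id, "no loss information"))
        if r.binaural_loss_pct is not None:
            if not 0.0 <= r.binaural_loss_pct <= 100.0:
                report.violations.append(
                    Violation(r.id, f"binaural_loss_pct {r.binaural_loss_pct} outside [0, 100]")
                )
            elif r.loss_group is not None:
                implied = str(discretize_binaural_loss(r.binaural_loss_pct))
                if implied != canonical_loss_group(r.loss_group):
                    report.violations.append(
                        Violation(
                            r.id,
                            f"loss_group {r.loss_group} inconsistent with "
                            f"binaural_loss_pct {r.binaural_loss_pct} (implies group {implied})",
                        )
                    )
    return report
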