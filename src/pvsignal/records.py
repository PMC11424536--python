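"""In-memory representation of spontaneous adverse-event reports.

A spontaneous reporting system stores one *case* per patient/event episode;
cases are revised over time, so several *reports* (versions) of the same
case can coexist in the raw quarterly extracts. Each report carries
demographics, one or more drug entries with a role code, the reported
reactions coded as MedDRA Preferred Terms (PTs), outcome codes and
per-drug indications.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from datetime import date

#: FAERS drug role codes: Primary Suspect, Secondary Suspect,
#: Concomitant, Interacting.
ROLE_CODES = ("PS", "SS", "C", "I")

#: FAERS outcome codes: death, life-threatening, hospitalization,
#: disability, congenital anomaly, required intervention, other serious.
OUTCOME_CODES = ("DE", "LT", "HO", "DS", "CA", "RI", "OT")

SEX_VALUES = ("female", "male", "unknown")
REPORTER_TYPES = ("physician", "pharmacist", "consumer", "other", "unknown")


@dataclass
class DrugEntry:
    """One drug line of a report.

    ``raw_name`` is the verbatim string from the reporter;
    ``standardized_name`` is filled in by curation (dictionary lookup).
    """

    drug_seq: int
    raw_name: str
    role: str  # one of ROLE_CODES
    standardized_name: str | None = None

    def __post_init__(self) -> None:
        if not self.raw_name:
            raise ValueError("DrugEntry.raw_name must be non-empty")
        if self.role not in ROLE_CODES:
            raise ValueError(f"invalid role code {self.role!r}")


@dataclass
class RawRecord:
    """One parsed line of a quarterly table, before assembly into reports."""

    report_id: str
    case_id: str | None
    values: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.report_id:
            raise ValueError("RawRecord.report_id must be non-empty")


@dataclass
class ReportRecord:
    """One assembled (and possibly curated) adverse-event report."""

    report_id: str
    case_id: str | None = None
    case_version: int = 0
    receipt_date: date | None = None
    sex: str = "unknown"
    age_years: float | None = None
    reporter_type: str = "unknown"
    reporter_country: str = "unknown"
    drugs: list[DrugEntry] = field(default_factory=list)
    reactions: list[str] = field(default_factory=list)
    outcomes: list[str] = field(default_factory=list)
    indications: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.report_id:
            raise ValueError("ReportRecord.report_id must be non-empty")
        if self.case_version < 0:
            raise ValueError("case_version must be >= 0")
        if self.age_years is not None and not (0 <= self.age_years < 150):
            raise ValueError("age_years must be in [0, 150)")
        if len(set(self.outcomes)) != len(self.outcomes):
            raise ValueError("outcomes must not contain duplicates")

    def has_drug(self, standardized_name: str, role: str | None = None) -> bool:
        """True if any drug entry matches the standardized name (and role)."""
        for entry in self.drugs:
            if entry.standardized_name == standardized_name and (
                role is None or entry.role == role
            ):
                return True
        return False

    def copy(self) -> "ReportRecord":
        return copy.deepcopy(self)
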