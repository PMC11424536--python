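"""Descriptive summaries of a curated target-drug report set.

Produces the usual "Table 1" of a pharmacovigilance study: sex, age
group, reporter type, reporter country, indication and outcome
distributions. Report-level variables use the number of reports as the
denominator (with "unknown" as an explicit category); outcomes and
indications use the number of records, since one report may carry
several.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .errors import ConfigurationError
from .records import ReportRecord

logger = logging.getLogger(__name__)

AGE_GROUPS = ("<18", "18–45", "45–65", "≥65", "unknown")

VARIABLES = (
    "sex", "age_group", "reporter_type", "reporter_country",
    "outcome", "indication",
)


@dataclass
class FrequencyTable:
    """Counts and percentages of one categorical variable."""

    variable: str
    rows: list[tuple[str, int, float]]  # (category, count, percent)
    denominator: int
    denominator_description: str

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.rows, columns=["category", "count", "percent"])
        frame.insert(0, "variable", self.variable)
        return frame


def bin_age(age_years: float | None) -> str:
    """Age group of a report; half-open bins, lower bound inclusive.

    [0, 18) -> "<18", [18, 45) -> "18–45", [45, 65) -> "45–65",
    [65, inf) -> ">=65"; missing or negative -> "unknown".
    """
    if age_years is None:
        return "unknown"
    if age_years < 0:
        logger.warning("negative age %r binned as unknown", age_years)
        return "unknown"
    if age_years < 18:
        return "<18"
    if age_years < 45:
        return "18–45"
    if age_years < 65:
        return "45–65"
    return "≥65"


def _values_for(report: ReportRecord, variable: str) -> Iterable[str]:
    if variable == "sex":
        return (report.sex,)
    if variable == "age_group":
        return (bin_age(report.age_years),)
    if variable == "reporter_type":
        return (report.reporter_type,)
    if variable == "reporter_country":
        return (report.reporter_country,)
    if variable == "outcome":
        return tuple(report.outcomes)
    if variable == "indication":
        return tuple(pt for _seq, pt in report.indications)
    raise ConfigurationError(f"unknown descriptive variable {variable!r}")


def summarize_categorical(
    reports: Sequence[ReportRecord], variable: str
) -> FrequencyTable:
    """Frequency table of one variable over a curated report set.

    For report-level variables (sex, age_group, reporter_type,
    reporter_country) the denominator is the number of reports; for
    outcome/indication it is the total number of such records. Rows are
    sorted by count descending (ties by label) and percentages are
    rounded to two decimals. An empty input yields an empty table with
    denominator 0.
    """
    if variable not in VARIABLES:
        raise ConfigurationError(f"unknown descriptive variable {variable!r}")
    counts: dict[str, int] = {}
    n_records = 0
    for report in reports:
        for value in _values_for(report, variable):
            counts[value] = counts.get(value, 0) + 1
            n_records += 1
    per_record = variable in ("outcome", "indication")
    denominator = n_records if per_record else len(reports)
    description = (
        f"total {variable} records" if per_record else "number of reports"
    )
    rows = [
        (category, count,
         round(100.0 * count / denominator, 2) if denominator else 0.0)
        for category, count in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return FrequencyTable(
        variable=variable, rows=rows,
        denominator=denominator, denominator_description=description,
    )


def table1(reports: Sequence[ReportRecord]) -> pd.DataFrame:
    """Combined descriptive table across all supported variables."""
    frames = [summarize_categorical(reports, var).to_frame() for var in VARIABLES]
    return pd.concat(frames, ignore_index=True)
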