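"""Table schemas for the two quarterly-extract dialects.

FAERS quarterly ASCII extracts changed layout in 2012Q4 when the legacy
LAERS system was retired: legacy files are keyed by ISR (one integer per
report version, case number in a ``CASE`` column) while current files are
keyed by PRIMARYID (case id concatenated with the version number) and
carry an explicit CASEVERSION column. Analyses spanning the changeover
must read both dialects.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import SchemaError

TABLE_NAMES = ("DEMO", "DRUG", "REAC", "OUTC", "INDI", "RPSR", "THER")
DIALECTS = ("legacy", "current")


@dataclass(frozen=True)
class TableSchema:
    """Column layout of one quarterly table in one dialect."""

    table_name: str
    dialect: str
    column_names: tuple[str, ...]
    key_column: str
    case_column: str | None = None

    def __post_init__(self) -> None:
        if self.table_name not in TABLE_NAMES:
            raise ValueError(f"unknown table {self.table_name!r}")
        if self.dialect not in DIALECTS:
            raise ValueError(f"unknown dialect {self.dialect!r}")
        if not self.column_names:
            raise ValueError("column_names must be non-empty")
        lowered = [c.lower() for c in self.column_names]
        if len(set(lowered)) != len(lowered):
            raise ValueError("column_names must be unique")
        if self.key_column.lower() not in lowered:
            raise ValueError("key_column must be one of column_names")
        if self.case_column and self.case_column.lower() not in lowered:
            raise ValueError("case_column must be one of column_names")


def _schema(table: str, dialect: str, cols: tuple[str, ...],
            key: str, case: str | None) -> TableSchema:
    return TableSchema(table, dialect, cols, key, case)


#: Default layouts. A practical subset of the official column lists —
#: every field the downstream analysis consumes, in the official order.
DEFAULT_SCHEMAS: dict[tuple[str, str], TableSchema] = {
    ("DEMO", "current"): _schema(
        "DEMO", "current",
        ("primaryid", "caseid", "caseversion", "fda_dt", "age", "age_cod",
         "sex", "occp_cod", "occr_country"),
        "primaryid", "caseid"),
    ("DRUG", "current"): _schema(
        "DRUG", "current",
        ("primaryid", "caseid", "drug_seq", "role_cod", "drugname"),
        "primaryid", "caseid"),
    ("REAC", "current"): _schema(
        "REAC", "current", ("primaryid", "caseid", "pt"),
        "primaryid", "caseid"),
    ("OUTC", "current"): _schema(
        "OUTC", "current", ("primaryid", "caseid", "outc_cod"),
        "primaryid", "caseid"),
    ("INDI", "current"): _schema(
        "INDI", "current",
        ("primaryid", "caseid", "indi_drug_seq", "indi_pt"),
        "primaryid", "caseid"),
    ("DEMO", "legacy"): _schema(
        "DEMO", "legacy",
        ("ISR", "CASE", "FDA_DT", "AGE", "AGE_COD", "GNDR_COD",
         "OCCP_COD", "REPORTER_COUNTRY"),
        "ISR", "CASE"),
    ("DRUG", "legacy"): _schema(
        "DRUG", "legacy",
        ("ISR", "DRUG_SEQ", "ROLE_COD", "DRUGNAME"),
        "ISR", None),
    ("REAC", "legacy"): _schema(
        "REAC", "legacy", ("ISR", "PT"), "ISR", None),
    ("OUTC", "legacy"): _schema(
        "OUTC", "legacy", ("ISR", "OUTC_COD"), "ISR", None),
    ("INDI", "legacy"): _schema(
        "INDI", "legacy", ("ISR", "DRUG_SEQ", "INDI_PT"), "ISR", None),
}

#: Quarter of the LAERS -> FAERS layout change.
DIALECT_CHANGE = (2012, 4)


def dialect_for_quarter(quarter: str) -> str:
    """Default dialect for a quarter label like ``"2012Q3"``."""
    year, q = parse_quarter(quarter)
    return "legacy" if (year, q) < DIALECT_CHANGE else "current"


def parse_quarter(quarter: str) -> tuple[int, int]:
    """``"2004Q1"`` -> ``(2004, 1)``; raises on malformed labels."""
    try:
        year_s, q_s = quarter.upper().split("Q")
        year, q = int(year_s), int(q_s)
    except (ValueError, AttributeError) as exc:
        raise ValueError(f"malformed quarter label {quarter!r}") from exc
    if not 1 <= q <= 4:
        raise ValueError(f"malformed quarter label {quarter!r}")
    return year, q


def schema_for(table_name: str, dialect: str) -> TableSchema:
    try:
        return DEFAULT_SCHEMAS[(table_name.upper(), dialect)]
    except KeyError:
        raise SchemaError(
            f"no default schema for table {table_name!r}, dialect {dialect!r}"
        ) from None


def detect_schema(table_name: str, header_fields: list[str]) -> TableSchema:
    """Pick the dialect whose schema matches a header (order-insensitive).

    Raises :class:`SchemaError` naming the first unmatched column when
    neither dialect matches.
    """
    got = {f.lower() for f in header_fields}
    first_error: SchemaError | None = None
    for dialect in DIALECTS:
        schema = DEFAULT_SCHEMAS.get((table_name.upper(), dialect))
        if schema is None:
            continue
        want = {c.lower() for c in schema.column_names}
        if got == want:
            return schema
        if first_error is None:
            unmatched = [h.lower() for h in header_fields if h.lower() not in want]
            unmatched += sorted(want - got)
            first_error = SchemaError(
                f"{table_name} header does not match {dialect} schema; "
                f"first unmatched column: {unmatched[0]!r}"
            )
    assert first_error is not None
    raise first_error
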