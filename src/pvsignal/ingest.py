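"""Parsing of "$"-delimited quarterly tables and assembly into reports.

The quarterly extracts are plain text: one header line, then one record
per line, fields separated by ``$``. ``parse_table`` turns one table into
:class:`~pvsignal.records.RawRecord` rows; ``assemble_reports`` joins the
DEMO/DRUG/REAC/OUTC/INDI tables on the report key into
:class:`~pvsignal.records.ReportRecord` objects.
"""

from __future__ import annotations

import logging
from datetime import date
from typing import Iterable, Mapping, Sequence, TextIO

from .errors import ParseError, SchemaError
from .records import OUTCOME_CODES, ROLE_CODES, DrugEntry, RawRecord, ReportRecord
from .schemas import TableSchema

logger = logging.getLogger(__name__)

#: Conversion of FAERS AGE_COD units into years.
AGE_DIVISORS = {
    "DEC": 0.1,       # decades: multiply by 10
    "YR": 1.0,
    "MON": 12.0,
    "WK": 52.143,
    "DY": 365.25,
    "HR": 8766.0,
}

_SEX_MAP = {"F": "female", "M": "male"}
_OCCP_MAP = {"MD": "physician", "PH": "pharmacist", "CN": "consumer",
             "OT": "other", "HP": "other", "LW": "other"}


def parse_table(stream: TextIO | Iterable[str], schema: TableSchema) -> list[RawRecord]:
    """Parse one "$"-delimited table into raw records, in file order.

    The header must be a case-insensitive permutation of
    ``schema.column_names``; a row with more or fewer fields than the
    header is a :class:`ParseError` carrying the 1-based line number.
    Empty fields are treated as missing and omitted from ``values``.
    """
    lines = iter(stream)
    try:
        header_line = next(lines)
    except StopIteration:
        raise ParseError("empty stream: no header line", 1) from None
    header = [h.strip().lower() for h in header_line.rstrip("\r\n").split("$")]

    want = {c.lower() for c in schema.column_names}
    got = set(header)
    if got != want or len(header) != len(schema.column_names):
        unmatched = [h for h in header if h not in want]
        unmatched += sorted(want - got)
        label = unmatched[0] if unmatched else header[0]
        raise SchemaError(
            f"header does not match schema for {schema.table_name} "
            f"({schema.dialect}); first unmatched column: {label!r}"
        )

    key_col = schema.key_column.lower()
    case_col = schema.case_column.lower() if schema.case_column else None

    records: list[RawRecord] = []
    for lineno, line in enumerate(lines, start=2):
        line = line.rstrip("\r\n")
        if not line:
            continue
        fields = line.split("$")
        if len(fields) != len(header):
            raise ParseError(
                f"expected {len(header)} fields, got {len(fields)}", lineno
            )
        values = {col: val.strip() for col, val in zip(header, fields) if val.strip()}
        report_id = values.get(key_col, "")
        if not report_id:
            raise ParseError(f"missing key field {key_col!r}", lineno)
        case_id = values.get(case_col) if case_col else None
        records.append(RawRecord(report_id=report_id, case_id=case_id, values=values))
    return records


def convert_age(age_text: str, age_cod: str | None) -> float | None:
    """Convert a raw AGE/AGE_COD pair to years; None when unusable."""
    try:
        value = float(age_text)
    except (TypeError, ValueError):
        return None
    cod = (age_cod or "YR").upper()
    divisor = AGE_DIVISORS.get(cod)
    if divisor is None:
        return None
    years = value / divisor
    if not 0 <= years < 150:
        return None
    # keep integral ages as exact floats for clean round trips
    return years


def _parse_date(text: str | None) -> date | None:
    if not text or not text.isdigit():
        return None
    try:
        if len(text) == 8:
            return date(int(text[:4]), int(text[4:6]), int(text[6:8]))
        if len(text) == 6:
            return date(int(text[:4]), int(text[4:6]), 1)
        if len(text) == 4:
            return date(int(text), 1, 1)
    except ValueError:
        return None
    return None


def _get(values: Mapping[str, str], *names: str) -> str | None:
    for name in names:
        if name in values:
            return values[name]
    return None


def assemble_reports(
    tables: Mapping[str, Sequence[RawRecord]],
    counters: dict[str, int] | None = None,
) -> list[ReportRecord]:
    """Join raw table records on report id into assembled reports.

    DEMO, DRUG and REAC must be present (REAC rows may be absent for an
    individual report; curation decides what to do with reaction-less
    reports). DRUG/REAC/OUTC/INDI rows whose report id has no DEMO row
    are dropped and counted as orphans in ``counters`` and the log.
    """
    tables = {name.upper(): rows for name, rows in tables.items()}
    for required in ("DEMO", "DRUG", "REAC"):
        if required not in tables:
            raise SchemaError(f"required table {required} missing")

    reports: dict[str, ReportRecord] = {}
    orphans = 0
    bad_age = 0

    for row in tables["DEMO"]:
        v = row.values
        age = convert_age(_get(v, "age"), _get(v, "age_cod"))
        if _get(v, "age") is not None and age is None:
            bad_age += 1
        version_text = _get(v, "caseversion")
        try:
            version = int(version_text) if version_text else 0
        except ValueError:
            version = 0
        sex_raw = (_get(v, "sex", "gndr_cod") or "").upper()
        occp = (_get(v, "occp_cod") or "").upper()
        country = _get(v, "occr_country", "reporter_country")
        reports[row.report_id] = ReportRecord(
            report_id=row.report_id,
            case_id=row.case_id,
            case_version=version,
            receipt_date=_parse_date(_get(v, "fda_dt")),
            sex=_SEX_MAP.get(sex_raw, "unknown"),
            age_years=age,
            reporter_type=_OCCP_MAP.get(occp, "unknown"),
            reporter_country=country or "unknown",
        )

    for row in tables["DRUG"]:
        report = reports.get(row.report_id)
        if report is None:
            orphans += 1
            continue
        v = row.values
        seq_text = _get(v, "drug_seq")
        try:
            seq = int(seq_text) if seq_text else len(report.drugs) + 1
        except ValueError:
            seq = len(report.drugs) + 1
        role = (_get(v, "role_cod") or "C").upper()
        if role not in ROLE_CODES:
            role = "C"
        name = _get(v, "drugname")
        if not name:
            continue
        report.drugs.append(DrugEntry(drug_seq=seq, raw_name=name, role=role))

    for row in tables["REAC"]:
        report = reports.get(row.report_id)
        if report is None:
            orphans += 1
            continue
        pt = _get(row.values, "pt")
        if pt:
            report.reactions.append(pt)

    for row in tables.get("OUTC", ()):
        report = reports.get(row.report_id)
        if report is None:
            orphans += 1
            continue
        code = (_get(row.values, "outc_cod") or "").upper()
        if code in OUTCOME_CODES and code not in report.outcomes:
            report.outcomes.append(code)

    for row in tables.get("INDI", ()):
        report = reports.get(row.report_id)
        if report is None:
            orphans += 1
            continue
        v = row.values
        seq_text = _get(v, "indi_drug_seq", "drug_seq")
        pt = _get(v, "indi_pt")
        if not pt:
            continue
        try:
            seq = int(seq_text) if seq_text else 1
        except ValueError:
            seq = 1
        report.indications.append((seq, pt))

    for report in reports.values():
        report.drugs.sort(key=lambda entry: entry.drug_seq)

    if orphans:
        logger.info("dropped %d orphan rows with no DEMO record", orphans)
    if counters is not None:
        counters["orphan_rows"] = counters.get("orphan_rows", 0) + orphans
        counters["unparseable_ages"] = counters.get("unparseable_ages", 0) + bad_age
    return list(reports.values())
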