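"""Case curation: deduplication, drug-name standardization, PS filtering,
and PT -> SOC mapping.

Spontaneous reports are noisy: the same case is resubmitted in revised
versions, drug names arrive as free text (brand names, dose strings,
spelling variants), and reactions are coded at the MedDRA Preferred Term
(PT) level while safety review also works at the System Organ Class (SOC)
level. This module implements the curation chain applied before any
counting: keep only the latest version of each case, map raw drug strings
to standardized ingredient names through a synonym dictionary, restrict
the analysis set to reports where the target drug is the Primary Suspect,
and map PTs to their primary SOC.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Iterable, Sequence

from .errors import ConfigurationError
from .records import ReportRecord

logger = logging.getLogger(__name__)

#: Sentinel SOC for PTs absent from the loaded MedDRA map.
UNMAPPED = "UNMAPPED"

_DOSE_UNITS = {
    "mg", "g", "mcg", "ug", "kg", "ml", "l", "iu", "meq",
    "unit", "units", "mgs",
}
_FORM_TOKENS = {
    "tab", "tabs", "tablet", "tablets", "cap", "caps", "capsule",
    "capsules", "oral", "injection", "solution", "suspension",
}
_NUMBER_RE = re.compile(r"^\d+(?:\.\d+)?$")
_FUSED_DOSE_RE = re.compile(r"^\d+(?:\.\d+)?(?:%s)$" % "|".join(_DOSE_UNITS))
# keep "." so decimal doses like "2.5 mg" stay one token
_NON_ALNUM_RE = re.compile(r"[^0-9a-z.]+")


def normalize_drug_name(raw: str) -> str:
    """Normalize a raw drug string for dictionary lookup.

    Case-fold, collapse punctuation to spaces, drop dose tokens
    (a number followed by a unit, or fused like ``500mg``) and
    pharmaceutical-form tokens.
    """
    text = _NON_ALNUM_RE.sub(" ", raw.casefold()).strip()
    tokens = [t for t in (tok.strip(".") for tok in text.split()) if t]
    kept: list[str] = []
    i = 0
    while i < len(tokens):
        tok = tokens[i]
        if _FUSED_DOSE_RE.match(tok):
            i += 1
            continue
        if (
            _NUMBER_RE.match(tok)
            and i + 1 < len(tokens)
            and tokens[i + 1] in _DOSE_UNITS
        ):
            i += 2
            continue
        if tok in _FORM_TOKENS:
            i += 1
            continue
        kept.append(tok)
        i += 1
    return " ".join(kept)


def _load_two_column_tsv(path: str | Path, what: str) -> dict[str, str]:
    mapping: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ConfigurationError(
                    f"{what} {path}: line {lineno} is not two tab-separated columns"
                )
            mapping[parts[0]] = parts[1]
    return mapping


@dataclass
class SynonymDictionary:
    """Maps normalized raw drug names to standardized ingredient names."""

    mapping: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        # keys are stored normalized; normalizing again is a no-op for
        # pre-normalized dictionaries and a safety net otherwise
        self.mapping = {
            normalize_drug_name(k): v for k, v in self.mapping.items()
        }

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SynonymDictionary":
        """Load from a two-column TSV (raw_name TAB standardized_name)."""
        return cls(_load_two_column_tsv(path, "synonym dictionary"))

    def lookup(self, raw_name: str) -> str | None:
        return self.mapping.get(normalize_drug_name(raw_name))

    def __len__(self) -> int:
        return len(self.mapping)


@dataclass
class MeddraMap:
    """Maps a MedDRA PT (name or code) to its primary SOC.

    The package ships no MedDRA content; the map is loaded from a
    user-supplied two-column TSV (PT TAB SOC). Lookup is
    case-insensitive.
    """

    mapping: dict[str, str] = field(default_factory=dict)
    version: str = "unspecified"

    def __post_init__(self) -> None:
        self._folded = {k.casefold(): v for k, v in self.mapping.items()}

    @classmethod
    def from_tsv(cls, path: str | Path, version: str = "unspecified") -> "MeddraMap":
        return cls(_load_two_column_tsv(path, "MedDRA map"), version=version)

    def soc_of(self, pt: str) -> str:
        return self._folded.get(pt.casefold(), UNMAPPED)

    def __len__(self) -> int:
        return len(self.mapping)


def map_soc(pt: str, meddra: MeddraMap) -> str:
    """Primary SOC of a PT, or the ``UNMAPPED`` sentinel."""
    return meddra.soc_of(pt)


def _numeric_or_zero(text: str | None) -> int:
    if text and text.isdigit():
        return int(text)
    return 0


def _dedup_sort_key(report: ReportRecord):
    return (
        report.case_version,
        report.receipt_date or date.min,
        _numeric_or_zero(report.report_id),
        report.report_id,
    )


def _case_order_key(report: ReportRecord):
    cid = report.case_id
    if cid is None:
        return (2, 0, report.report_id)
    if cid.isdigit():
        return (0, int(cid), cid)
    return (1, 0, cid)


def deduplicate(
    reports: Sequence[ReportRecord],
    counters: dict[str, int] | None = None,
) -> list[ReportRecord]:
    """Keep the latest version of each case.

    Within a case id the kept report is the one with the highest case
    version; ties are broken by latest receipt date, then by the largest
    numeric report id. Reports without a case id are kept as singletons.
    Output is sorted by case id. Idempotent.
    """
    by_case: dict[str, list[ReportRecord]] = {}
    singletons: list[ReportRecord] = []
    for report in reports:
        if report.case_id is None:
            singletons.append(report)
        else:
            by_case.setdefault(report.case_id, []).append(report)

    kept = [max(group, key=_dedup_sort_key) for group in by_case.values()]
    discarded = len(reports) - len(kept) - len(singletons)
    if discarded:
        logger.info("deduplication discarded %d earlier case versions", discarded)
    if counters is not None:
        counters["discarded_versions"] = counters.get("discarded_versions", 0) + discarded
    return sorted(kept + singletons, key=_case_order_key)


def standardize_drugs(
    reports: Sequence[ReportRecord],
    dictionary: SynonymDictionary,
    counters: dict[str, int] | None = None,
) -> Sequence[ReportRecord]:
    """Set each drug entry's standardized name via dictionary lookup.

    Raw names missing from the dictionary fall back to their normalized
    form and are counted as unmapped. Mutates the entries in place and
    returns the same sequence.
    """
    if len(dictionary) == 0:
        raise ConfigurationError("synonym dictionary is empty")
    hits = misses = 0
    for report in reports:
        for entry in report.drugs:
            mapped = dictionary.lookup(entry.raw_name)
            if mapped is not None:
                entry.standardized_name = mapped
                hits += 1
            else:
                entry.standardized_name = normalize_drug_name(entry.raw_name)
                misses += 1
    total = hits + misses
    if total:
        logger.info(
            "drug standardization hit rate %.1f%% (%d/%d)",
            100.0 * hits / total, hits, total,
        )
    if counters is not None:
        counters["unmapped_drug_names"] = counters.get("unmapped_drug_names", 0) + misses
        counters["mapped_drug_names"] = counters.get("mapped_drug_names", 0) + hits
    return reports


def filter_primary_suspect(
    reports: Iterable[ReportRecord], drug: str
) -> list[ReportRecord]:
    """Reports where ``drug`` appears with the Primary Suspect role."""
    return [r for r in reports if r.has_drug(drug, role="PS")]


def drop_empty_reactions(
    reports: Iterable[ReportRecord],
    counters: dict[str, int] | None = None,
) -> list[ReportRecord]:
    """Remove reports with no reaction PT (they contribute to no cell)."""
    kept = [r for r in reports if r.reactions]
    dropped = 0
    if hasattr(reports, "__len__"):
        dropped = len(reports) - len(kept)  # type: ignore[arg-type]
    if dropped:
        logger.info("dropped %d reports with no reactions", dropped)
    if counters is not None:
        counters["reactionless_reports"] = counters.get("reactionless_reports", 0) + dropped
    return kept
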