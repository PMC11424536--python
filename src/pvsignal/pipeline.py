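"""End-to-end orchestration: ingest -> curation -> statistics -> outputs.

``run_pipeline`` reads every quarterly table file in a directory tree
(optionally restricted to a quarter range), assembles and curates the
reports, computes PT- and SOC-level disproportionality for the target
drug, and writes:

* ``table1.csv`` — descriptive distributions of the target-drug reports,
* ``pt_signals.csv`` / ``soc_signals.csv`` — the four statistics and
  flags per event, in rank order,
* ``topk.csv`` — the top-k positive PTs by the ranking statistic,
* ``manifest.json`` — config echo and the counts at every stage, so the
  run's headline numbers (reports analyzed, PTs flagged, SOCs involved)
  are directly inspectable.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .curation import (
    UNMAPPED,
    MeddraMap,
    SynonymDictionary,
    deduplicate,
    drop_empty_reactions,
    filter_primary_suspect,
    normalize_drug_name,
    standardize_drugs,
)
from .descriptives import table1
from .disproportionality import (
    BCPNNPriors,
    CriteriaConfig,
    build_tables,
    evaluate_signals,
    fit_mgps,
    rank_top_k,
    results_to_frame,
)
from .errors import PipelineError
from .ingest import assemble_reports, parse_table
from .records import RawRecord, ReportRecord
from .schemas import detect_schema, parse_quarter

logger = logging.getLogger(__name__)

_FILE_RE = re.compile(r"^(DEMO|DRUG|REAC|OUTC|INDI)(\d{2})Q([1-4])\.(txt|TXT)$")

FLOAT_FORMAT = "%.4f"


@dataclass
class PipelineConfig:
    """Everything a reproducible run needs."""

    input_dir: str | Path
    drug: str
    dictionary_path: str | Path
    meddra_path: str | Path | None = None
    out_dir: str | Path = "pvsignal_out"
    quarters: tuple[str, str] = ("2004Q1", "2023Q4")
    criteria: CriteriaConfig = field(default_factory=CriteriaConfig)
    priors: BCPNNPriors = field(default_factory=BCPNNPriors)
    ebgm_mode: str = "simplified"
    top_k: int = 30
    rank_key: str = "ror"
    log_level: str = "INFO"
    seed: int = 0

    def __post_init__(self) -> None:
        lo = parse_quarter(self.quarters[0])
        hi = parse_quarter(self.quarters[1])
        if lo > hi:
            raise ValueError(f"empty quarter range {self.quarters}")


def discover_quarter_files(
    input_dir: str | Path, quarters: tuple[str, str] = ("2004Q1", "2023Q4")
) -> dict[str, list[Path]]:
    """Find ``TABLEyyQq.txt`` files under ``input_dir`` within the range."""
    lo = parse_quarter(quarters[0])
    hi = parse_quarter(quarters[1])
    found: dict[str, list[Path]] = {}
    for path in sorted(Path(input_dir).rglob("*")):
        m = _FILE_RE.match(path.name)
        if not m:
            continue
        table, yy, q = m.group(1), int(m.group(2)), int(m.group(3))
        year = 2000 + yy  # the supported window starts in 2004
        if not lo <= (year, q) <= hi:
            continue
        found.setdefault(table, []).append(path)
    return found


def load_reports(
    input_dir: str | Path,
    quarters: tuple[str, str] = ("2004Q1", "2023Q4"),
    counters: dict[str, int] | None = None,
    encoding: str = "latin-1",
) -> list[ReportRecord]:
    """Parse and assemble every discovered quarterly file.

    The dialect of each file is detected from its header, so mixed
    legacy/current inputs are fine.
    """
    files = discover_quarter_files(input_dir, quarters)
    if "DEMO" not in files:
        raise PipelineError(f"no DEMO quarterly files found under {input_dir}")
    raw: dict[str, list[RawRecord]] = {}
    for table, paths in files.items():
        rows: list[RawRecord] = []
        for path in paths:
            with open(path, encoding=encoding, errors="replace") as fh:
                header = fh.readline().rstrip("\r\n").split("$")
                schema = detect_schema(table, header)
                fh.seek(0)
                rows.extend(parse_table(fh, schema))
        raw[table] = rows
    return assemble_reports(raw, counters=counters)


def run_pipeline(cfg: PipelineConfig) -> dict[str, object]:
    """Run the full analysis and write the artifact set.

    Returns the manifest dictionary (also written as JSON). Raises
    :class:`PipelineError` when no target-drug Primary Suspect reports
    remain after curation.
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    counters: dict[str, int] = {}
    written: list[str] = []

    reports = load_reports(cfg.input_dir, cfg.quarters, counters=counters)
    n_raw = len(reports)

    reports = deduplicate(reports, counters=counters)
    n_dedup = len(reports)

    dictionary = SynonymDictionary.from_tsv(cfg.dictionary_path)
    standardize_drugs(reports, dictionary, counters=counters)
    reports = drop_empty_reactions(reports, counters=counters)

    meddra = MeddraMap.from_tsv(cfg.meddra_path) if cfg.meddra_path else None

    drug = normalize_drug_name(cfg.drug)
    target = filter_primary_suspect(reports, drug)
    n_target = len(target)
    if n_target == 0:
        raise PipelineError(
            f"no reports with {cfg.drug!r} as Primary Suspect after curation"
        )

    # descriptive table of the target-drug reports
    table1(target).to_csv(out_dir / "table1.csv", index=False,
                          float_format=FLOAT_FORMAT)
    written.append("table1.csv")

    pt_tables = build_tables(reports, drug, level="PT", meddra=meddra)
    pt_results = evaluate_signals(
        pt_tables, level="PT", priors=cfg.priors, criteria=cfg.criteria,
        ebgm_mode=cfg.ebgm_mode, meddra=meddra,
        mgps_prior=(_fit_database_prior(reports, meddra)
                    if cfg.ebgm_mode == "mgps" else None),
    )
    pt_frame = results_to_frame(pt_results, key=cfg.rank_key)
    pt_frame.to_csv(out_dir / "pt_signals.csv", index=False,
                    float_format=FLOAT_FORMAT)
    written.append("pt_signals.csv")

    top = rank_top_k(pt_results, cfg.top_k, key=cfg.rank_key)
    results_to_frame(top, key=cfg.rank_key).to_csv(
        out_dir / "topk.csv", index=False, float_format=FLOAT_FORMAT
    )
    written.append("topk.csv")

    soc_frame = None
    if meddra is not None:
        soc_tables = build_tables(reports, drug, level="SOC", meddra=meddra)
        soc_results = evaluate_signals(
            soc_tables, level="SOC", priors=cfg.priors, criteria=cfg.criteria,
            ebgm_mode="simplified",
        )
        soc_frame = results_to_frame(soc_results, key=cfg.rank_key)
        soc_frame.to_csv(out_dir / "soc_signals.csv", index=False,
                         float_format=FLOAT_FORMAT)
        written.append("soc_signals.csv")

    flagged = [r for r in pt_results if r.overall_positive]
    socs_of_flagged = sorted(
        {r.soc for r in flagged if r.soc and r.soc != UNMAPPED}
    )
    unmapped_pts = sum(
        1 for r in pt_results if meddra is not None and r.soc == UNMAPPED
    )

    manifest = {
        "config": {
            "input_dir": str(cfg.input_dir),
            "quarters": list(cfg.quarters),
            "drug": cfg.drug,
            "dictionary": str(cfg.dictionary_path),
            "meddra": str(cfg.meddra_path) if cfg.meddra_path else None,
            "ebgm_mode": cfg.ebgm_mode,
            "criteria": vars(cfg.criteria) | {
                "combine_rule": list(cfg.criteria.combine_rule)
                if not isinstance(cfg.criteria.combine_rule, str)
                else cfg.criteria.combine_rule
            },
            "top_k": cfg.top_k,
            "rank_key": cfg.rank_key,
            "seed": cfg.seed,
        },
        "counts": {
            "raw_reports": n_raw,
            "deduplicated_reports": n_dedup,
            "target_ps_reports": n_target,
            "pts_analyzed": len(pt_results),
            "pts_flagged": len(flagged),
            "socs_of_flagged_pts": len(socs_of_flagged),
            "unmapped_pts": unmapped_pts,
            **counters,
        },
        "outputs": sorted(written + ["manifest.json"]),
    }
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info(
        "pipeline done: %d raw -> %d deduplicated -> %d target PS reports; "
        "%d PTs analyzed, %d flagged across %d SOCs",
        n_raw, n_dedup, n_target, len(pt_results), len(flagged),
        len(socs_of_flagged),
    )
    return manifest


def _fit_database_prior(reports: Sequence[ReportRecord], meddra):
    """Fit the MGPS prior on every (PS drug, PT) cell of the database."""
    drugs = sorted({
        d.standardized_name for r in reports for d in r.drugs
        if d.role == "PS" and d.standardized_name
    })
    tables = []
    for drug in drugs:
        tables.extend(build_tables(reports, drug, level="PT").values())
    return fit_mgps(tables)
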