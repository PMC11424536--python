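"""Synthetic spontaneous-reporting-system generator.

Generates quarterly extract files from a known probabilistic model so the
whole pipeline is testable offline and recovery of injected parameters
can be checked:

* each report gets one Primary Suspect drug drawn from ``drug_weights``
  (plus optional concomitant drugs), and its reaction PTs are drawn
  without replacement from a per-drug event distribution
  ``q_d(e) ∝ event_weights(e) * lambda(d, e)`` — drug and event are
  independent in the background (lambda = 1) and selected pairs carry a
  multiplicative relative-risk ``lambda > 1`` via :class:`SignalSpec`;
* demographics are drawn independently of drug/event assignment, from
  configurable categorical distributions;
* a configurable fraction of cases is re-emitted as 2–3 versions with
  possibly different raw drug spellings, exercising deduplication and
  name standardization; the intended final report per case is returned
  as ground truth;
* files are written in either quarterly dialect, byte-identically for a
  fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigurationError
from .records import DrugEntry, ReportRecord
from .schemas import parse_quarter, schema_for

# ---------------------------------------------------------------------------
# default vocabularies

#: Toy PT -> SOC pairs used for realistic-looking fixtures. This is an
#: invented miniature ontology, not MedDRA content.
CURATED_PTS: tuple[tuple[str, str], ...] = (
    ("Stevens-Johnson syndrome", "Skin and subcutaneous tissue disorders"),
    ("Dermatitis exfoliative", "Skin and subcutaneous tissue disorders"),
    ("Acute febrile neutrophilic dermatosis", "Skin and subcutaneous tissue disorders"),
    ("Oculomucocutaneous syndrome", "Skin and subcutaneous tissue disorders"),
    ("Rash", "Skin and subcutaneous tissue disorders"),
    ("Agranulocytosis", "Blood and lymphatic system disorders"),
    ("Anaemia folate deficiency", "Blood and lymphatic system disorders"),
    ("Lymphocytosis", "Blood and lymphatic system disorders"),
    ("Eosinophilia", "Blood and lymphatic system disorders"),
    ("Crystalluria", "Renal and urinary disorders"),
    ("Membranous glomerulonephritis", "Renal and urinary disorders"),
    ("Glomerulonephritis", "Renal and urinary disorders"),
    ("Eosinophilic pneumonia", "Respiratory, thoracic and mediastinal disorders"),
    ("Acute interstitial pneumonitis", "Respiratory, thoracic and mediastinal disorders"),
    ("Pulmonary eosinophilia", "Respiratory, thoracic and mediastinal disorders"),
    ("Necrotising fasciitis streptococcal", "Infections and infestations"),
    ("Mononucleosis syndrome", "Infections and infestations"),
    ("Neutropenic sepsis", "Infections and infestations"),
    ("Aseptic meningitis", "Nervous system disorders"),
    ("Headache", "Nervous system disorders"),
    ("Nausea", "Gastrointestinal disorders"),
    ("Vomiting", "Gastrointestinal disorders"),
    ("Diarrhoea", "Gastrointestinal disorders"),
    ("Pyrexia", "General disorders and administration site conditions"),
)

_SOC_POOL: tuple[str, ...] = tuple(dict.fromkeys(soc for _, soc in CURATED_PTS)) + (
    "Hepatobiliary disorders",
    "Immune system disorders",
    "Musculoskeletal and connective tissue disorders",
    "Cardiac disorders",
    "Investigations",
)

DEFAULT_DRUG_NAMES: tuple[str, ...] = (
    "sulfasalazine", "methotrexate", "ibuprofen", "prednisone",
    "omeprazole", "amoxicillin", "metformin", "atorvastatin",
    "lisinopril", "simvastatin",
)

#: Raw-spelling variants per standardized drug name. All variants
#: normalize back to the canonical name through the emitted dictionary.
DEFAULT_VARIANTS: dict[str, list[str]] = {
    "sulfasalazine": [
        "sulfasalazine", "SULFASALAZINE", "Sulfasalazine 500 MG",
        "AZULFIDINE", "Azulfidine EN-tabs", "SALAZOPYRIN",
        "sulphasalazine", "SULFASALAZINE TAB",
    ],
}

#: Categorical distributions of the demographic model. Report-level
#: fields include an explicit "unknown" mass; outcome/indication
#: categories are record-level.
DEFAULT_DEMOGRAPHICS: dict[str, dict] = {
    "sex": {"female": 0.6806, "male": 0.2641, "unknown": 0.0553},
    "age_group": {"<18": 0.05, "18–45": 0.30, "45–65": 0.3503,
                  "≥65": 0.20, "unknown": 0.0997},
    "reporter_type": {"physician": 0.3839, "pharmacist": 0.12,
                      "consumer": 0.27, "other": 0.15, "unknown": 0.0761},
    "reporter_country": {"US": 0.38, "CA": 0.10, "JP": 0.08, "GB": 0.06,
                         "DE": 0.04, "FR": 0.04, "unknown": 0.30},
    "outcome": {"OT": 0.5195, "HO": 0.3213, "LT": 0.0606, "DS": 0.0455,
                "DE": 0.0400, "CA": 0.0100, "RI": 0.0031},
    # at most one outcome record per report by default: sampling several
    # without replacement would distort the record-level category shares
    # away from the configured ones
    "outcome_count": {0: 0.30, 1: 0.70},
    "indication": {"Rheumatoid arthritis": 0.3349, "Ulcerative colitis": 0.20,
                   "Crohn's disease": 0.12, "Ankylosing spondylitis": 0.10,
                   "Psoriatic arthropathy": 0.06,
                   "Product used for unknown indication": 0.1851},
    "indication_present": 0.8,
}

_AGE_RANGES = {"<18": (1, 17), "18–45": (18, 44), "45–65": (45, 64), "≥65": (65, 90)}


def default_drug_names(n_drugs: int) -> list[str]:
    names = list(DEFAULT_DRUG_NAMES[:n_drugs])
    names += [f"drug_{i + 1:03d}" for i in range(len(names), n_drugs)]
    return names


def default_variant_table(drug_names: Sequence[str]) -> dict[str, list[str]]:
    table: dict[str, list[str]] = {}
    for name in drug_names:
        if name in DEFAULT_VARIANTS:
            table[name] = list(DEFAULT_VARIANTS[name])
        else:
            table[name] = [name, name.upper(), f"{name.title()} 100 MG"]
    return table


def default_event_catalog(n_events: int) -> list[tuple[str, str]]:
    """PT names with their toy-SOC assignment; curated names first."""
    catalog = list(CURATED_PTS[:n_events])
    for i in range(len(catalog), n_events):
        catalog.append((f"PT_{i + 1:03d}", _SOC_POOL[i % len(_SOC_POOL)]))
    return catalog


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class SignalSpec:
    """A (drug index, event index, relative risk) injection triple."""

    drug: int
    event: int
    rr: float

    def __post_init__(self) -> None:
        if self.rr <= 0:
            raise ValueError("relative risk must be > 0")


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic reporting-system model."""

    n_reports: int = 5000
    n_drugs: int = 8
    n_events: int = 150
    drug_weights: Sequence[float] | None = None
    event_weights: Sequence[float] | None = None
    events_per_report_mean: float = 1.8
    events_per_report_max: int = 10
    demographics: Mapping[str, dict] | None = None
    duplicate_fraction: float = 0.1
    name_variant_table: Mapping[str, list[str]] | None = None
    drug_names: Sequence[str] | None = None
    event_catalog: Sequence[tuple[str, str]] | None = None
    dialect: str = "current"
    quarter: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reports <= 0:
            raise ValueError("n_reports must be positive")
        if self.dialect not in ("legacy", "current"):
            raise ValueError(f"unknown dialect {self.dialect!r}")
        if not 0 <= self.duplicate_fraction < 1:
            raise ValueError("duplicate_fraction must be in [0, 1)")
        for name, weights, k in (
            ("drug_weights", self.drug_weights, self.n_drugs),
            ("event_weights", self.event_weights, self.n_events),
        ):
            if weights is not None:
                weights = np.asarray(weights, dtype=float)
                if weights.shape != (k,):
                    raise ValueError(f"{name} must have length {k}")
                if abs(weights.sum() - 1.0) > 1e-9 or np.any(weights < 0):
                    raise ValueError(f"{name} must be a probability vector")
        if self.quarter is None:
            self.quarter = "2012Q1" if self.dialect == "legacy" else "2023Q4"
        if self.drug_names is None:
            self.drug_names = default_drug_names(self.n_drugs)
        if self.event_catalog is None:
            self.event_catalog = default_event_catalog(self.n_events)
        if self.name_variant_table is None:
            self.name_variant_table = default_variant_table(self.drug_names)
        if self.demographics is None:
            self.demographics = DEFAULT_DEMOGRAPHICS

    @property
    def event_names(self) -> list[str]:
        return [pt for pt, _soc in self.event_catalog]

    @property
    def meddra_pairs(self) -> list[tuple[str, str]]:
        return list(self.event_catalog)


# ---------------------------------------------------------------------------
# sampling


def _resolve_weights(
    weights: Sequence[float] | None, k: int, rng: np.random.Generator
) -> np.ndarray:
    if weights is not None:
        return np.asarray(weights, dtype=float)
    # symmetric Dirichlet draw: realistic unequal reporting frequencies
    return rng.dirichlet(np.full(k, 2.0))


def _categorical(dist: Mapping[str, float]) -> tuple[list, np.ndarray]:
    labels = list(dist.keys())
    probs = np.asarray(list(dist.values()), dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9 or np.any(probs < 0):
        raise ConfigurationError(f"probabilities must sum to 1, got {probs.sum()}")
    return labels, probs


def sample_reports(
    cfg: GeneratorConfig, signals: Sequence[SignalSpec] = ()
) -> list[ReportRecord]:
    """Draw a synthetic report set from the generator model.

    Deterministic for a fixed ``cfg.seed``. Each report has one Primary
    Suspect drug and 1+ reactions; injected :class:`SignalSpec` triples
    multiply the target drug's event weights before renormalization.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_reports
    n_drugs, n_events = cfg.n_drugs, cfg.n_events

    drug_w = _resolve_weights(cfg.drug_weights, n_drugs, rng)
    event_w = _resolve_weights(cfg.event_weights, n_events, rng)

    lam = np.ones((n_drugs, n_events))
    for sig in signals:
        if not (0 <= sig.drug < n_drugs and 0 <= sig.event < n_events):
            raise ConfigurationError(
                f"signal ({sig.drug}, {sig.event}) out of range"
            )
        lam[sig.drug, sig.event] = sig.rr

    drug_idx = rng.choice(n_drugs, size=n, p=drug_w)

    k_max = min(cfg.events_per_report_max, n_events)
    k_counts = rng.geometric(1.0 / cfg.events_per_report_mean, size=n)
    k_counts = np.minimum(k_counts, k_max)

    # weighted sampling without replacement via Gumbel-perturbed log-weights
    event_lists: list[np.ndarray] = [np.empty(0, dtype=int)] * n
    log_event_w = np.log(np.maximum(event_w, 1e-300))
    for d in range(n_drugs):
        rows = np.nonzero(drug_idx == d)[0]
        if len(rows) == 0:
            continue
        gumbel = rng.gumbel(size=(len(rows), n_events))
        keys = gumbel + log_event_w + np.log(lam[d])
        order = np.argsort(-keys, axis=1)[:, :k_max]
        for pos, i in enumerate(rows):
            event_lists[i] = order[pos, : k_counts[i]]

    demo = cfg.demographics
    sex_labels, sex_p = _categorical(demo["sex"])
    sex_idx = rng.choice(len(sex_labels), size=n, p=sex_p)
    age_labels, age_p = _categorical(demo["age_group"])
    age_grp_idx = rng.choice(len(age_labels), size=n, p=age_p)
    age_u = rng.random(n)
    rep_labels, rep_p = _categorical(demo["reporter_type"])
    rep_idx = rng.choice(len(rep_labels), size=n, p=rep_p)
    cty_labels, cty_p = _categorical(demo["reporter_country"])
    cty_idx = rng.choice(len(cty_labels), size=n, p=cty_p)

    outc_labels, outc_p = _categorical(demo["outcome"])
    count_labels, count_p = _categorical(
        {str(k): v for k, v in demo["outcome_count"].items()}
    )
    outc_counts = np.array([int(c) for c in count_labels])[
        rng.choice(len(count_labels), size=n, p=count_p)
    ]
    outc_keys = rng.gumbel(size=(n, len(outc_labels))) + np.log(outc_p)
    outc_order = np.argsort(-outc_keys, axis=1)

    ind_labels, ind_p = _categorical(demo["indication"])
    ind_present = rng.random(n) < float(demo["indication_present"])
    ind_idx = rng.choice(len(ind_labels), size=n, p=ind_p)

    year, q = parse_quarter(cfg.quarter)
    quarter_start = date(year, 3 * (q - 1) + 1, 1)
    day_offsets = rng.integers(0, 89, size=n)

    n_conc_choices = np.array([0, 1, 2])
    n_conc = n_conc_choices[rng.choice(3, size=n, p=[0.5, 0.3, 0.2])]
    conc_raw = rng.integers(0, max(n_drugs - 1, 1), size=(n, 2))
    conc_roles = rng.choice(["SS", "C", "I"], size=(n, 2))

    variant_table = cfg.name_variant_table
    drug_names = list(cfg.drug_names)
    variant_u = rng.random(n)

    is_current = cfg.dialect == "current"
    event_names = cfg.event_names

    reports: list[ReportRecord] = []
    for i in range(n):
        d = int(drug_idx[i])
        name = drug_names[d]
        variants = variant_table.get(name, [name])
        raw = variants[int(variant_u[i] * len(variants))]
        drugs = [DrugEntry(drug_seq=1, raw_name=raw, role="PS")]
        if n_drugs > 1:
            for j in range(int(n_conc[i])):
                other = int(conc_raw[i, j])
                if other >= d:
                    other += 1  # skip the PS drug
                drugs.append(
                    DrugEntry(
                        drug_seq=2 + j,
                        raw_name=drug_names[other],
                        role=str(conc_roles[i, j]),
                    )
                )
        age_group = age_labels[age_grp_idx[i]]
        if age_group == "unknown":
            age: float | None = None
        else:
            lo, hi = _AGE_RANGES[age_group]
            age = float(lo + int(age_u[i] * (hi - lo + 1)))

        case_id = str(10_000_001 + i)
        version = 1 if is_current else 0
        report_id = (
            f"{case_id}{version}" if is_current else str(70_000_001 + 10 * i)
        )
        outcomes = [outc_labels[j] for j in outc_order[i, : outc_counts[i]]]
        reports.append(
            ReportRecord(
                report_id=report_id,
                case_id=case_id,
                case_version=version,
                receipt_date=quarter_start + timedelta(days=int(day_offsets[i])),
                sex=sex_labels[sex_idx[i]],
                age_years=age,
                reporter_type=rep_labels[rep_idx[i]],
                reporter_country=cty_labels[cty_idx[i]],
                drugs=drugs,
                reactions=[event_names[j] for j in event_lists[i]],
                outcomes=outcomes,
                indications=[(1, ind_labels[ind_idx[i]])] if ind_present[i] else [],
            )
        )
    return reports


def inject_duplicates_and_variants(
    reports: Sequence[ReportRecord], cfg: GeneratorConfig
) -> tuple[list[ReportRecord], dict[str, ReportRecord]]:
    """Re-emit a fraction of cases as extra versions.

    Each selected case gains 1–2 later versions (2–3 versions total)
    with a possibly different raw spelling of the suspect drug; in the
    legacy dialect versions are distinguished by receipt date and report
    id only (case_version stays 0). Returns the expanded report list and
    the ground truth: case id -> the intended final report.
    """
    rng = np.random.default_rng([cfg.seed, 7])
    n = len(reports)
    n_dup = int(round(cfg.duplicate_fraction * n))
    dup_positions = set(
        rng.choice(n, size=n_dup, replace=False).tolist() if n_dup else []
    )
    is_current = cfg.dialect == "current"
    variant_table = cfg.name_variant_table

    out: list[ReportRecord] = []
    ground_truth: dict[str, ReportRecord] = {}
    for i, report in enumerate(reports):
        out.append(report)
        final = report
        if i in dup_positions:
            n_versions = int(rng.integers(2, 4))
            for v in range(2, n_versions + 1):
                dup = report.copy()
                if is_current:
                    dup.case_version = v
                    dup.report_id = f"{dup.case_id}{v}"
                else:
                    dup.report_id = str(int(report.report_id) + (v - 1))
                if report.receipt_date is not None:
                    dup.receipt_date = report.receipt_date + timedelta(days=30 * (v - 1))
                ps = dup.drugs[0]
                variants = variant_table.get(ps.raw_name, None)
                if variants is None:
                    # raw name is already a variant; find its canonical list
                    for _canon, vlist in variant_table.items():
                        if ps.raw_name in vlist:
                            variants = vlist
                            break
                if variants:
                    ps.raw_name = variants[int(rng.random() * len(variants))]
                out.append(dup)
                final = dup
        ground_truth[report.case_id] = final.copy()
    return out, ground_truth


# ---------------------------------------------------------------------------
# file output


_SEX_OUT = {"female": "F", "male": "M", "unknown": ""}
_OCCP_OUT = {"physician": "MD", "pharmacist": "PH", "consumer": "CN",
             "other": "OT", "unknown": ""}


def _fmt_age(age: float | None) -> str:
    if age is None:
        return ""
    if age == int(age):
        return str(int(age))
    return f"{age:.10g}"


def _fmt_date(d: date | None) -> str:
    return d.strftime("%Y%m%d") if d else ""


def _check(value: str) -> str:
    if "$" in value:
        raise ValueError(f"field value contains the delimiter: {value!r}")
    return value


def write_faers_quarter(
    reports: Sequence[ReportRecord],
    directory: str | Path,
    dialect: str,
    quarter: str | None = None,
) -> dict[str, Path]:
    """Write DEMO/DRUG/REAC/OUTC/INDI files in the "$"-delimited format.

    Returns table name -> path. The written files round-trip exactly
    through :func:`pvsignal.ingest.parse_table` +
    :func:`pvsignal.ingest.assemble_reports`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if quarter is None:
        quarter = "2012Q1" if dialect == "legacy" else "2023Q4"
    year, q = parse_quarter(quarter)
    suffix = f"{year % 100:02d}Q{q}"

    lines: dict[str, list[str]] = {t: [] for t in ("DEMO", "DRUG", "REAC", "OUTC", "INDI")}
    for table in lines:
        schema = schema_for(table, dialect)
        lines[table].append("$".join(schema.column_names))

    current = dialect == "current"
    for r in reports:
        rid, cid = _check(r.report_id), _check(r.case_id or "")
        country = "" if r.reporter_country == "unknown" else r.reporter_country
        demo_fields = (
            [rid, cid, str(r.case_version), _fmt_date(r.receipt_date),
             _fmt_age(r.age_years), "YR" if r.age_years is not None else "",
             _SEX_OUT[r.sex], _OCCP_OUT[r.reporter_type], country]
            if current else
            [rid, cid, _fmt_date(r.receipt_date),
             _fmt_age(r.age_years), "YR" if r.age_years is not None else "",
             _SEX_OUT[r.sex], _OCCP_OUT[r.reporter_type], country]
        )
        lines["DEMO"].append("$".join(_check(f) for f in demo_fields))
        for drug in r.drugs:
            fields = [rid, cid, str(drug.drug_seq), drug.role, drug.raw_name] \
                if current else [rid, str(drug.drug_seq), drug.role, drug.raw_name]
            lines["DRUG"].append("$".join(_check(f) for f in fields))
        for pt in r.reactions:
            fields = [rid, cid, pt] if current else [rid, pt]
            lines["REAC"].append("$".join(_check(f) for f in fields))
        for code in r.outcomes:
            fields = [rid, cid, code] if current else [rid, code]
            lines["OUTC"].append("$".join(_check(f) for f in fields))
        for seq, pt in r.indications:
            fields = [rid, cid, str(seq), pt] if current else [rid, str(seq), pt]
            lines["INDI"].append("$".join(_check(f) for f in fields))

    paths: dict[str, Path] = {}
    for table, rows in lines.items():
        path = directory / f"{table}{suffix}.txt"
        path.write_text("\n".join(rows) + "\n", encoding="latin-1", newline="\n")
        paths[table] = path
    return paths


def write_synonym_dictionary(
    variant_table: Mapping[str, Sequence[str]], path: str | Path
) -> Path:
    """Write the raw-name -> standardized-name dictionary TSV."""
    path = Path(path)
    rows = ["# raw_name\tstandardized_name"]
    for canonical, variants in variant_table.items():
        for variant in dict.fromkeys([canonical, *variants]):
            rows.append(f"{variant}\t{canonical}")
    path.write_text("\n".join(rows) + "\n", encoding="utf-8")
    return path


def write_meddra_map(
    pairs: Sequence[tuple[str, str]], path: str | Path
) -> Path:
    """Write the toy PT -> SOC map TSV (synthetic miniature ontology)."""
    path = Path(path)
    rows = ["# pt\tsoc"]
    rows += [f"{pt}\t{soc}" for pt, soc in pairs]
    path.write_text("\n".join(rows) + "\n", encoding="utf-8")
    return path


def write_ground_truth(
    ground_truth: Mapping[str, ReportRecord],
    reports: Sequence[ReportRecord],
    path: str | Path,
) -> Path:
    """Sidecar CSV: case_id, suspect drug (raw), events, duplicated flag."""
    case_counts: dict[str, int] = {}
    for r in reports:
        case_counts[r.case_id] = case_counts.get(r.case_id, 0) + 1
    path = Path(path)
    rows = ["case_id,drug,events,duplicated"]
    for case_id in sorted(ground_truth, key=lambda c: int(c) if c.isdigit() else 0):
        final = ground_truth[case_id]
        ps = next((d for d in final.drugs if d.role == "PS"), None)
        rows.append(
            ",".join([
                case_id,
                (ps.raw_name if ps else "").replace(",", " "),
                ";".join(final.reactions).replace(",", " "),
                str(case_counts.get(case_id, 1) > 1),
            ])
        )
    path.write_text("\n".join(rows) + "\n", encoding="utf-8")
    return path


def generate_dataset(
    cfg: GeneratorConfig,
    signals: Sequence[SignalSpec] = (),
    out_dir: str | Path = ".",
) -> dict[str, object]:
    """Full bundle: quarter files, dictionary, toy MedDRA map, ground truth.

    Returns the written paths plus the in-memory report list and ground
    truth for direct use in tests and scripts.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    reports = sample_reports(cfg, signals)
    reports, ground_truth = inject_duplicates_and_variants(reports, cfg)
    paths = write_faers_quarter(reports, out_dir, cfg.dialect, cfg.quarter)
    dict_path = write_synonym_dictionary(
        cfg.name_variant_table, out_dir / "drug_dictionary.tsv"
    )
    meddra_path = write_meddra_map(cfg.meddra_pairs, out_dir / "meddra_map.tsv")
    gt_path = write_ground_truth(ground_truth, reports, out_dir / "ground_truth.csv")
    return {
        "tables": paths,
        "dictionary": dict_path,
        "meddra": meddra_path,
        "ground_truth_csv": gt_path,
        "reports": reports,
        "ground_truth": ground_truth,
    }
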