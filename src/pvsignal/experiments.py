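"""Seeded simulation experiments on the synthetic reporting system.

These are the package's built-in operating-characteristic checks:
coverage of the ROR confidence interval for injected relative risks, and
the false-positive rate of the combined signal criteria on a null
database. Both run the full generator -> curation -> statistics path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .curation import SynonymDictionary, standardize_drugs
from .disproportionality import (
    CriteriaConfig,
    build_tables,
    compute_ror,
    evaluate_signals,
)
from .synthetic import GeneratorConfig, SignalSpec, sample_reports

#: Study design of the recovery experiment: a common target drug in a
#: moderate database; ~200 events keep the within-report renormalization
#: bias of the injected relative risk well inside the CI half-width.
RECOVERY_DESIGN = dict(
    n_reports=6000,
    n_drugs=4,
    n_events=200,
    drug_weights=(0.25, 0.25, 0.25, 0.25),
    duplicate_fraction=0.0,
)

#: Study design of the null-calibration experiment: uniform background,
#: no injected signals, event counts large enough that many pairs clear
#: the expected-count floor.
NULL_DESIGN = dict(
    n_reports=5000,
    n_drugs=8,
    n_events=100,
    duplicate_fraction=0.0,
)


def _dictionary_for(cfg: GeneratorConfig) -> SynonymDictionary:
    return SynonymDictionary({
        variant: canonical
        for canonical, variants in cfg.name_variant_table.items()
        for variant in variants
    })


@dataclass
class CoverageResult:
    rr: float
    n_replicates: int
    n_covered: int
    median_ror: float
    mean_a: float

    @property
    def coverage(self) -> float:
        return self.n_covered / self.n_replicates


def ror_coverage(
    rr: float,
    n_replicates: int = 100,
    base_seed: int = 0,
    target_drug: str = "sulfasalazine",
) -> CoverageResult:
    """Fraction of seeded replicates whose ROR 95% CI covers ``rr``.

    Each replicate generates a fresh synthetic database with one
    injected (target drug, event 0) signal, standardizes the raw names,
    builds the contingency table and checks the Woolf interval.
    """
    uniform = np.full(
        RECOVERY_DESIGN["n_events"], 1.0 / RECOVERY_DESIGN["n_events"]
    )
    covered = 0
    rors: list[float] = []
    a_counts: list[int] = []
    for i in range(n_replicates):
        cfg = GeneratorConfig(
            event_weights=uniform, seed=base_seed + i, **RECOVERY_DESIGN
        )
        reports = sample_reports(cfg, [SignalSpec(0, 0, rr)])
        standardize_drugs(reports, _dictionary_for(cfg))
        tables = build_tables(reports, target_drug)
        table = tables.get(cfg.event_names[0])
        if table is None:
            continue
        ror, lo, hi = compute_ror(table)
        covered += lo <= rr <= hi
        rors.append(ror)
        a_counts.append(table.a)
    return CoverageResult(
        rr=rr,
        n_replicates=n_replicates,
        n_covered=covered,
        median_ror=float(np.median(rors)) if rors else float("nan"),
        mean_a=float(np.mean(a_counts)) if a_counts else float("nan"),
    )


@dataclass
class NullCalibrationResult:
    n_replicates: int
    n_pairs_eligible: int
    n_pairs_flagged: int

    @property
    def flagged_fraction(self) -> float:
        if self.n_pairs_eligible == 0:
            return float("nan")
        return self.n_pairs_flagged / self.n_pairs_eligible


def null_flag_rate(
    n_replicates: int = 20,
    base_seed: int = 0,
    min_expected: float = 3.0,
    criteria: CriteriaConfig | None = None,
) -> NullCalibrationResult:
    """False-positive rate of the combined criteria on null databases.

    Generates signal-free databases, evaluates every (drug, event) pair
    whose expected a-count under independence is at least
    ``min_expected``, and pools the fraction flagged overall-positive.
    """
    criteria = criteria or CriteriaConfig()
    uniform_d = np.full(NULL_DESIGN["n_drugs"], 1.0 / NULL_DESIGN["n_drugs"])
    uniform_e = np.full(NULL_DESIGN["n_events"], 1.0 / NULL_DESIGN["n_events"])
    eligible = flagged = 0
    for i in range(n_replicates):
        cfg = GeneratorConfig(
            drug_weights=uniform_d, event_weights=uniform_e,
            seed=base_seed + i, **NULL_DESIGN,
        )
        reports = sample_reports(cfg)
        standardize_drugs(reports, _dictionary_for(cfg))
        for drug in cfg.drug_names:
            tables = build_tables(reports, drug)
            keep = {e: t for e, t in tables.items() if t.expected >= min_expected}
            results = evaluate_signals(keep, criteria=criteria)
            eligible += len(results)
            flagged += sum(r.overall_positive for r in results)
    return NullCalibrationResult(
        n_replicates=n_replicates,
        n_pairs_eligible=eligible,
        n_pairs_flagged=flagged,
    )
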