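"""Disproportionality statistics for drug–event pairs.

For each event (PT or SOC) reported at least once with the target drug,
the report-level 2x2 contingency table is

    ============================  =========  ===========
                                  event      other events
    target drug (Primary Suspect)   a            b
    all other reports               c            d
    ============================  =========  ===========

with N = a + b + c + d. Four estimators of disproportionate reporting
are computed:

* **ROR** — reporting odds ratio ``ad/bc`` with a Woolf (log-scale)
  95% confidence interval.
* **PRR** — proportional reporting ratio ``[a/(a+b)] / [c/(c+d)]``
  together with the Pearson chi-square of the table.
* **BCPNN IC** — the information component ``log2 P(drug,event) /
  (P(drug)P(event))`` under independent Beta posteriors with the
  standard calibrated priors; IC025 is its lower 95% credibility bound
  via the closed-form variance approximation.
* **EBGM** — the empirical Bayes geometric mean of the relative
  reporting ratio. The default "simplified" mode is the raw
  observed/expected ratio ``aN/((a+b)(a+c))`` with a log-scale 5th
  percentile; the opt-in MGPS mode fits DuMouchel's two-component
  gamma-mixture prior across all database cells and shrinks each cell's
  ratio toward it.

A pair is flagged a *positive signal* when it satisfies the configured
criteria (by default: ROR CI lower bound > 1 with at least 3 reports;
PRR above its threshold with chi-square > 4 and at least 3 reports;
IC025 > 0; EBGM05 > 2; combined with AND).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .curation import UNMAPPED, MeddraMap
from .errors import ConfigurationError
from .records import ReportRecord

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# contingency tables


@dataclass(frozen=True)
class ContingencyTable:
    """Report-level 2x2 counts for one (drug, event) pair."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            value = getattr(self, name)
            if value != int(value) or value < 0:
                raise ValueError(f"cell {name} must be a non-negative integer")
        if self.n == 0:
            raise ValueError("empty table (N = 0)")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def expected(self) -> float:
        """Expected a-count under independence: (a+b)(a+c)/N."""
        return (self.a + self.b) * (self.a + self.c) / self.n

    @property
    def has_zero_cell(self) -> bool:
        return min(self.a, self.b, self.c, self.d) == 0


def _cells(t: ContingencyTable, zero_correction: bool) -> tuple[float, float, float, float] | None:
    """Cell values used for estimation.

    Applies the Haldane–Anscombe +0.5 continuity correction to all four
    cells when any cell is zero and correction is enabled; returns None
    when the table is degenerate and correction is disabled.
    """
    if not t.has_zero_cell:
        return float(t.a), float(t.b), float(t.c), float(t.d)
    if zero_correction:
        return t.a + 0.5, t.b + 0.5, t.c + 0.5, t.d + 0.5
    return None


def build_tables(
    reports: Sequence[ReportRecord],
    drug: str,
    level: str = "PT",
    meddra: MeddraMap | None = None,
) -> dict[str, ContingencyTable]:
    """Contingency tables for every event seen with the target drug.

    The background is the whole curated report set: ``a + b`` equals the
    number of reports with the target drug as Primary Suspect, ``a + c``
    the number of reports mentioning the event. Counting is report-level:
    an event repeated within one report counts once.
    """
    if level not in ("PT", "SOC"):
        raise ConfigurationError(f"unknown level {level!r}")
    if level == "SOC" and meddra is None:
        raise ConfigurationError("SOC-level analysis requires a MedDRA map")

    n_total = len(reports)
    n_target = 0
    target_counts: dict[str, int] = {}
    all_counts: dict[str, int] = {}
    for report in reports:
        is_target = report.has_drug(drug, role="PS")
        if is_target:
            n_target += 1
        if level == "PT":
            events = set(report.reactions)
        else:
            events = {meddra.soc_of(pt) for pt in report.reactions}
        for event in events:
            all_counts[event] = all_counts.get(event, 0) + 1
            if is_target:
                target_counts[event] = target_counts.get(event, 0) + 1

    tables: dict[str, ContingencyTable] = {}
    for event, a in sorted(target_counts.items()):
        c = all_counts[event] - a
        b = n_target - a
        d = n_total - a - b - c
        tables[event] = ContingencyTable(a=a, b=b, c=c, d=d)
    return tables


# ---------------------------------------------------------------------------
# frequentist estimators


class RorResult(NamedTuple):
    ror: float
    ci_low: float
    ci_high: float


class PrrResult(NamedTuple):
    prr: float
    chi2: float


def compute_ror(
    t: ContingencyTable, z: float = 1.96, zero_correction: bool = True
) -> RorResult:
    """Reporting odds ratio with Woolf 95% confidence interval.

    ROR = ad/bc; CI = exp(ln ROR ± z * sqrt(1/a + 1/b + 1/c + 1/d)).
    Zero cells trigger the +0.5 correction (or a NaN sentinel when
    disabled).
    """
    cells = _cells(t, zero_correction)
    if cells is None:
        return RorResult(math.nan, math.nan, math.nan)
    a, b, c, d = cells
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return RorResult(ror, ror * math.exp(-z * se), ror * math.exp(z * se))


def compute_prr_chi2(
    t: ContingencyTable, yates: bool = False, zero_correction: bool = True
) -> PrrResult:
    """Proportional reporting ratio and the table's Pearson chi-square.

    PRR = [a/(a+b)] / [c/(c+d)]; chi2 = N(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d)),
    without continuity correction unless ``yates`` is set.
    """
    cells = _cells(t, zero_correction)
    if cells is None:
        return PrrResult(math.nan, math.nan)
    a, b, c, d = cells
    n = a + b + c + d
    prr = (a / (a + b)) / (c / (c + d))
    diff = abs(a * d - b * c)
    if yates:
        diff = max(diff - n / 2, 0.0)
    chi2 = n * diff**2 / ((a + b) * (c + d) * (a + c) * (b + d))
    return PrrResult(prr, chi2)


def compute_ebgm_simplified(
    t: ContingencyTable, zero_correction: bool = True
) -> tuple[float, float]:
    """Observed/expected relative reporting ratio with a log-scale 5th pct.

    EBGM = aN / ((a+b)(a+c));
    EBGM05 = exp(ln EBGM - 1.645 * sqrt(1/a + 1/b + 1/c + 1/d)).
    """
    cells = _cells(t, zero_correction)
    if cells is None:
        return math.nan, math.nan
    a, b, c, d = cells
    n = a + b + c + d
    ebgm = a * n / ((a + b) * (a + c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return ebgm, ebgm * math.exp(-1.645 * se)


# ---------------------------------------------------------------------------
# BCPNN


@dataclass(frozen=True)
class BCPNNPriors:
    """Priors of the closed-form BCPNN (Bate-style) information component.

    ``gamma11``, ``alpha1``, ``beta1`` are the joint/marginal Beta prior
    pseudo-counts; ``alpha``/``beta`` the marginal denominators; the
    joint denominator gamma is calibrated per table so that IC = 0 under
    exact independence. ``z`` scales the credibility bound (1.96 for a
    two-sided 95% interval; 2.0 is a common alternative convention).
    """

    gamma11: float = 1.0
    alpha1: float = 1.0
    beta1: float = 1.0
    alpha: float = 2.0
    beta: float = 2.0
    z: float = 1.96

    def __post_init__(self) -> None:
        for name in ("gamma11", "alpha1", "beta1", "alpha", "beta", "z"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def compute_bcpnn(
    t: ContingencyTable, priors: BCPNNPriors | None = None
) -> tuple[float, float]:
    """Information component and its lower credibility bound.

    Uses the closed-form posterior-moment expressions with the joint
    prior denominator gamma calibrated from the margins, and the
    standard delta-method variance for the IC.
    """
    p = priors or BCPNNPriors()
    a, n = t.a, t.n
    row1 = t.a + t.b  # drug margin
    col1 = t.a + t.c  # event margin

    gamma = p.gamma11 * (n + p.alpha) * (n + p.beta) / (
        (row1 + p.alpha1) * (col1 + p.beta1)
    )
    ic = math.log2(
        (a + p.gamma11) * (n + p.alpha) * (n + p.beta)
        / ((n + gamma) * (row1 + p.alpha1) * (col1 + p.beta1))
    )
    var = (1 / math.log(2)) ** 2 * (
        (n - a + gamma - p.gamma11) / ((a + p.gamma11) * (1 + n + gamma))
        + (n - row1 + p.alpha - p.alpha1) / ((row1 + p.alpha1) * (1 + n + p.alpha))
        + (n - col1 + p.beta - p.beta1) / ((col1 + p.beta1) * (1 + n + p.beta))
    )
    return ic, ic - p.z * math.sqrt(var)


def sample_bcpnn_ic(
    t: ContingencyTable,
    priors: BCPNNPriors | None = None,
    n_draws: int = 100_000,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Monte-Carlo draws of the IC from the three independent Beta posteriors.

    Intended as an independent cross-check of :func:`compute_bcpnn`:
    draws p11 ~ Beta(a+gamma11, N-a+gamma-gamma11), p1. and p.1 from the
    corresponding marginal posteriors, and returns log2(p11/(p1. p.1)).
    """
    p = priors or BCPNNPriors()
    rng = rng or np.random.default_rng()
    a, n = t.a, t.n
    row1, col1 = t.a + t.b, t.a + t.c
    gamma = p.gamma11 * (n + p.alpha) * (n + p.beta) / (
        (row1 + p.alpha1) * (col1 + p.beta1)
    )
    p11 = rng.beta(a + p.gamma11, n - a + gamma - p.gamma11, size=n_draws)
    p1_ = rng.beta(row1 + p.alpha1, n - row1 + p.alpha - p.alpha1, size=n_draws)
    p_1 = rng.beta(col1 + p.beta1, n - col1 + p.beta - p.beta1, size=n_draws)
    return np.log2(p11 / (p1_ * p_1))


# ---------------------------------------------------------------------------
# MGPS (opt-in full-shrinkage EBGM)


@dataclass(frozen=True)
class MGPSPrior:
    """Two-component gamma-mixture prior on the relative reporting ratio.

    The prior density is ``P Ga(alpha1, beta1) + (1-P) Ga(alpha2, beta2)``
    (shape/rate parameterization); each component's marginal for an
    observed count with expectation E is negative binomial. ``p = 1``
    degenerates to a single gamma component.
    """

    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    p: float
    converged: bool = True

    def __post_init__(self) -> None:
        for name in ("alpha1", "beta1", "alpha2", "beta2"):
            value = getattr(self, name)
            if not (math.isfinite(value) and value > 0):
                raise ValueError(f"{name} must be positive and finite")
        if not 0 < self.p <= 1:
            raise ValueError("mixture weight p must be in (0, 1]")


_MGPS_START = (0.2, 0.1, 2.0, 4.0, 1.0 / 3.0)


def _mgps_loglik(params: np.ndarray, a: np.ndarray, e: np.ndarray) -> float:
    la1, lb1, la2, lb2, logit_p = params
    a1, b1 = math.exp(la1), math.exp(lb1)
    a2, b2 = math.exp(la2), math.exp(lb2)
    p = 1.0 / (1.0 + math.exp(-logit_p))
    # marginal: a ~ NB(shape, beta/(beta+E)) per component
    lp1 = stats.nbinom.logpmf(a, a1, b1 / (b1 + e))
    lp2 = stats.nbinom.logpmf(a, a2, b2 / (b2 + e))
    mix = np.logaddexp(math.log(p) + lp1, math.log1p(-p) + lp2)
    return -float(np.sum(mix))


def fit_mgps(
    tables: Iterable[ContingencyTable] | tuple[np.ndarray, np.ndarray],
    start: Sequence[float] = _MGPS_START,
) -> MGPSPrior:
    """Fit the gamma-mixture prior by marginal maximum likelihood.

    ``tables`` is either a sequence of contingency tables (one per
    (drug, event) cell of the database) or a pre-computed ``(a, E)``
    pair of arrays. Non-convergence issues a warning and returns the
    best parameters found, flagged via ``converged=False``.
    """
    if isinstance(tables, tuple) and len(tables) == 2:
        a_arr = np.asarray(tables[0], dtype=float)
        e_arr = np.asarray(tables[1], dtype=float)
    else:
        table_list = list(tables)
        a_arr = np.array([t.a for t in table_list], dtype=float)
        e_arr = np.array([t.expected for t in table_list], dtype=float)
    if a_arr.size < 2:
        raise ValueError("MGPS fit needs at least 2 cells")
    if np.any(e_arr <= 0):
        raise ValueError("expected counts must be positive")

    a1, b1, a2, b2, p = start
    x0 = np.array([math.log(a1), math.log(b1), math.log(a2), math.log(b2),
                   math.log(p / (1 - p))])
    with np.errstate(divide="ignore", invalid="ignore"):
        result = optimize.minimize(
            _mgps_loglik, x0, args=(a_arr, e_arr), method="Nelder-Mead",
            options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-10},
        )
    la1, lb1, la2, lb2, logit_p = result.x
    if not result.success:
        warnings.warn(
            "MGPS prior fit did not converge; returning best parameters found",
            RuntimeWarning,
            stacklevel=2,
        )
    return MGPSPrior(
        alpha1=math.exp(la1), beta1=math.exp(lb1),
        alpha2=math.exp(la2), beta2=math.exp(lb2),
        p=1.0 / (1.0 + math.exp(-logit_p)),
        converged=bool(result.success),
    )


def mgps_posterior(
    a: float, e: float, prior: MGPSPrior
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Posterior mixture over the relative reporting ratio for one cell.

    Returns (weights, shapes, rates): the posterior is
    ``w1 Ga(alpha1+a, beta1+E) + w2 Ga(alpha2+a, beta2+E)`` with weights
    proportional to the prior weights times the component marginals.
    """
    shapes = np.array([prior.alpha1 + a, prior.alpha2 + a])
    rates = np.array([prior.beta1 + e, prior.beta2 + e])
    if prior.p == 1.0:
        return np.array([1.0, 0.0]), shapes, rates
    log_m1 = stats.nbinom.logpmf(a, prior.alpha1, prior.beta1 / (prior.beta1 + e))
    log_m2 = stats.nbinom.logpmf(a, prior.alpha2, prior.beta2 / (prior.beta2 + e))
    logw = np.array([math.log(prior.p) + log_m1, math.log1p(-prior.p) + log_m2])
    logw -= special.logsumexp(logw)
    return np.exp(logw), shapes, rates


def mgps_posterior_mean(a: float, e: float, prior: MGPSPrior) -> float:
    """Posterior mean of the relative reporting ratio for one cell."""
    weights, shapes, rates = mgps_posterior(a, e, prior)
    return float(np.sum(weights * shapes / rates))


def compute_ebgm_mgps(
    t: ContingencyTable, prior: MGPSPrior
) -> tuple[float, float]:
    """Shrunken EBGM and its 5th posterior percentile for one table.

    EBGM is the posterior geometric mean ``exp(E[ln lambda | a])`` with
    ``E[ln lambda] = sum_k w_k (psi(alpha_k + a) - ln(beta_k + E))``;
    EBGM05 solves ``CDF(EBGM05) = 0.05`` on the posterior mixture by
    root finding.
    """
    a, e = t.a, t.expected
    weights, shapes, rates = mgps_posterior(a, e, prior)
    mean_log = float(np.sum(weights * (special.digamma(shapes) - np.log(rates))))
    ebgm = math.exp(mean_log)

    def mixture_cdf(x: float) -> float:
        return float(np.sum(weights * stats.gamma.cdf(x, shapes, scale=1.0 / rates)))

    ppf = stats.gamma.ppf(0.05, shapes, scale=1.0 / rates)
    lo, hi = float(np.min(ppf)), float(np.max(ppf))
    if math.isclose(lo, hi, rel_tol=1e-12):
        ebgm05 = lo
    else:
        ebgm05 = optimize.brentq(
            lambda x: mixture_cdf(x) - 0.05, lo * (1 - 1e-9), hi * (1 + 1e-9),
            xtol=1e-13, rtol=8.9e-16, maxiter=200,
        )
    return ebgm, float(ebgm05)


# ---------------------------------------------------------------------------
# criteria, results, ranking


@dataclass(frozen=True)
class CriteriaConfig:
    """Thresholds defining a positive signal.

    Defaults follow the common FAERS-mining convention: ROR CI lower
    bound > 1 with at least 3 reports; PRR above ``prr_gt`` (default 0;
    the ``evans2001`` preset uses 2) with chi-square > 4 and at least 3
    reports; IC025 > 0; EBGM05 > 2. ``combine_rule`` is ``"all_four"``
    (intersection), ``"any"``, or a tuple naming a subset of
    {"ror", "prr", "bcpnn", "ebgm"}.
    """

    min_reports: int = 3
    ror_ci_low_gt: float = 1.0
    prr_gt: float = 0.0
    chi2_gt: float = 4.0
    ic025_gt: float = 0.0
    ebgm05_gt: float = 2.0
    combine_rule: str | tuple[str, ...] = "all_four"

    def __post_init__(self) -> None:
        if self.min_reports < 1:
            raise ValueError("min_reports must be >= 1")
        for name in ("ror_ci_low_gt", "prr_gt", "chi2_gt", "ic025_gt", "ebgm05_gt"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if isinstance(self.combine_rule, str):
            if self.combine_rule not in ("all_four", "any"):
                raise ValueError(f"unknown combine_rule {self.combine_rule!r}")
        else:
            unknown = set(self.combine_rule) - {"ror", "prr", "bcpnn", "ebgm"}
            if unknown or not self.combine_rule:
                raise ValueError(f"invalid combine_rule subset {self.combine_rule!r}")

    @classmethod
    def paper(cls) -> "CriteriaConfig":
        """Default criteria (PRR magnitude threshold 0)."""
        return cls()

    @classmethod
    def evans2001(cls) -> "CriteriaConfig":
        """Conventional PRR >= 2 cut-off."""
        return cls(prr_gt=2.0)


PRESETS = {"paper": CriteriaConfig.paper, "evans2001": CriteriaConfig.evans2001}


@dataclass
class SignalResult:
    """All four estimators and per-criterion flags for one pair."""

    event: str
    level: str  # "PT" or "SOC"
    a: int
    b: int
    c: int
    d: int
    ror: float
    ror_ci95_low: float
    ror_ci95_high: float
    prr: float
    chi2: float
    ic: float
    ic025: float
    ebgm: float
    ebgm05: float
    corrected: bool = False
    soc: str | None = None
    ror_positive: bool = False
    prr_positive: bool = False
    bcpnn_positive: bool = False
    ebgm_positive: bool = False
    overall_positive: bool = False

    @property
    def n_reports(self) -> int:
        return self.a

    @property
    def flags(self) -> dict[str, bool]:
        return {
            "ror_positive": self.ror_positive,
            "prr_positive": self.prr_positive,
            "bcpnn_positive": self.bcpnn_positive,
            "ebgm_positive": self.ebgm_positive,
            "overall_positive": self.overall_positive,
        }


def evaluate_table(
    event: str,
    t: ContingencyTable,
    level: str = "PT",
    priors: BCPNNPriors | None = None,
    ebgm_mode: str = "simplified",
    mgps_prior: MGPSPrior | None = None,
    zero_correction: bool = True,
    soc: str | None = None,
) -> SignalResult:
    """Compute all four statistics for one (event, table) pair."""
    ror = compute_ror(t, zero_correction=zero_correction)
    prr = compute_prr_chi2(t, zero_correction=zero_correction)
    ic, ic025 = compute_bcpnn(t, priors)
    if ebgm_mode == "simplified":
        ebgm, ebgm05 = compute_ebgm_simplified(t, zero_correction=zero_correction)
    elif ebgm_mode == "mgps":
        if mgps_prior is None:
            raise ConfigurationError("ebgm_mode='mgps' requires a fitted MGPSPrior")
        ebgm, ebgm05 = compute_ebgm_mgps(t, mgps_prior)
    else:
        raise ConfigurationError(f"unknown ebgm_mode {ebgm_mode!r}")
    return SignalResult(
        event=event, level=level, a=t.a, b=t.b, c=t.c, d=t.d,
        ror=ror.ror, ror_ci95_low=ror.ci_low, ror_ci95_high=ror.ci_high,
        prr=prr.prr, chi2=prr.chi2, ic=ic, ic025=ic025,
        ebgm=ebgm, ebgm05=ebgm05,
        corrected=t.has_zero_cell and zero_correction,
        soc=soc,
    )


def evaluate_signals(
    tables: Mapping[str, ContingencyTable],
    level: str = "PT",
    priors: BCPNNPriors | None = None,
    criteria: CriteriaConfig | None = None,
    ebgm_mode: str = "simplified",
    mgps_prior: MGPSPrior | None = None,
    meddra: MeddraMap | None = None,
    zero_correction: bool = True,
) -> list[SignalResult]:
    """Evaluate every table and apply the positive-signal criteria."""
    results = [
        evaluate_table(
            event, t, level=level, priors=priors, ebgm_mode=ebgm_mode,
            mgps_prior=mgps_prior, zero_correction=zero_correction,
            soc=(meddra.soc_of(event) if (meddra and level == "PT") else None),
        )
        for event, t in tables.items()
    ]
    return apply_criteria(results, criteria or CriteriaConfig())


def apply_criteria(
    results: Sequence[SignalResult], cfg: CriteriaConfig | None = None
) -> list[SignalResult]:
    """Set the per-criterion and overall flags on each result."""
    cfg = cfg or CriteriaConfig()
    for r in results:
        enough = r.a >= cfg.min_reports
        r.ror_positive = bool(enough and r.ror_ci95_low > cfg.ror_ci_low_gt)
        r.prr_positive = bool(
            enough and r.prr > cfg.prr_gt and r.chi2 > cfg.chi2_gt
        )
        r.bcpnn_positive = bool(r.ic025 > cfg.ic025_gt)
        r.ebgm_positive = bool(r.ebgm05 > cfg.ebgm05_gt)
        per = {
            "ror": r.ror_positive,
            "prr": r.prr_positive,
            "bcpnn": r.bcpnn_positive,
            "ebgm": r.ebgm_positive,
        }
        if cfg.combine_rule == "all_four":
            r.overall_positive = all(per.values())
        elif cfg.combine_rule == "any":
            r.overall_positive = any(per.values())
        else:
            r.overall_positive = all(per[name] for name in cfg.combine_rule)
    return list(results)


def _rank_key(key: str):
    def sort_key(r: SignalResult):
        value = getattr(r, key)
        if isinstance(value, float) and math.isnan(value):
            value = -math.inf
        return (-value, -r.a, r.event)

    return sort_key


def rank_top_k(
    results: Sequence[SignalResult], k: int, key: str = "ror"
) -> list[SignalResult]:
    """Top-k positive signals ordered by a statistic.

    Filters to ``overall_positive``, sorts descending by ``key`` with
    ties broken by the a-count (descending) then event label
    (ascending); returns at most ``k`` results (empty for k <= 0).
    """
    if k <= 0:
        return []
    positives = [r for r in results if r.overall_positive]
    return sorted(positives, key=_rank_key(key))[:k]


_FRAME_COLUMNS = [
    "event", "soc", "a", "b", "c", "d",
    "ror", "ror_ci95_low", "ror_ci95_high", "prr", "chi2",
    "ic", "ic025", "ebgm", "ebgm05", "overall_positive", "flags", "corrected",
]


def results_to_frame(
    results: Sequence[SignalResult], key: str = "ror"
) -> pd.DataFrame:
    """Tabulate results as a DataFrame in rank order (positives first)."""
    ordered = sorted(
        results,
        key=lambda r: (not r.overall_positive,) + _rank_key(key)(r),
    )
    rows = []
    for r in ordered:
        positive_names = [
            name for name, flag in (
                ("ror", r.ror_positive), ("prr", r.prr_positive),
                ("bcpnn", r.bcpnn_positive), ("ebgm", r.ebgm_positive),
            ) if flag
        ]
        rows.append({
            "event": r.event,
            "soc": r.soc if r.soc is not None else (r.event if r.level == "SOC" else UNMAPPED),
            "a": r.a, "b": r.b, "c": r.c, "d": r.d,
            "ror": r.ror, "ror_ci95_low": r.ror_ci95_low,
            "ror_ci95_high": r.ror_ci95_high,
            "prr": r.prr, "chi2": r.chi2, "ic": r.ic, "ic025": r.ic025,
            "ebgm": r.ebgm, "ebgm05": r.ebgm05,
            "overall_positive": r.overall_positive,
            "flags": ";".join(positive_names),
            "corrected": r.corrected,
        })
    return pd.DataFrame(rows, columns=_FRAME_COLUMNS)
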