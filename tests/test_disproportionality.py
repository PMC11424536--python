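"""Contingency tables and the four disproportionality estimators."""

import math

import numpy as np
import pytest
from scipy import special, stats

from pvsignal import (
    BCPNNPriors,
    ConfigurationError,
    ContingencyTable,
    CriteriaConfig,
    MGPSPrior,
    apply_criteria,
    build_tables,
    compute_bcpnn,
    compute_ebgm_mgps,
    compute_ebgm_simplified,
    compute_prr_chi2,
    compute_ror,
    evaluate_table,
    fit_mgps,
    rank_top_k,
)
from pvsignal.disproportionality import (
    mgps_posterior,
    mgps_posterior_mean,
    sample_bcpnn_ic,
)

from conftest import make_report


def chi2_cellwise(t: ContingencyTable) -> float:
    """Independent oracle: Pearson chi-square as sum of (O-E)^2/E."""
    observed = np.array([[t.a, t.b], [t.c, t.d]], dtype=float)
    rows = observed.sum(axis=1, keepdims=True)
    cols = observed.sum(axis=0, keepdims=True)
    expected = rows * cols / observed.sum()
    return float(((observed - expected) ** 2 / expected).sum())


def random_tables(rng: np.random.Generator, n: int, a_min: int = 1):
    for _ in range(n):
        yield ContingencyTable(
            a=int(rng.integers(a_min, 100)),
            b=int(rng.integers(1, 500)),
            c=int(rng.integers(1, 500)),
            d=int(rng.integers(100, 20000)),
        )


class TestContingencyTable:
    def test_margins_and_expected(self):
        t = ContingencyTable(10, 90, 100, 9900)
        assert t.n == 10100
        assert t.expected == pytest.approx(100 * 110 / 10100)

    def test_rejects_negative_and_empty(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 0, 0, 1)
        with pytest.raises(ValueError):
            ContingencyTable(0, 0, 0, 0)


class TestBuildTables:
    def _reports(self):
        # five reports: X-PS:[E1,E2], X-PS:[E1], Y-PS:[E1], Y-PS:[E3], X-PS:[E3]
        specs = [
            ("X", ["E1", "E2"]), ("X", ["E1"]), ("Y", ["E1"]),
            ("Y", ["E3"]), ("X", ["E3"]),
        ]
        reports = []
        for i, (drug, events) in enumerate(specs):
            r = make_report(report_id=str(i), case_id=str(i),
                            drugs=[(drug, "PS")], reactions=events)
            r.drugs[0].standardized_name = drug
            reports.append(r)
        return reports

    def test_enumerated_counts(self):
        tables = build_tables(self._reports(), "X")
        assert (tables["E1"].a, tables["E1"].b, tables["E1"].c,
                tables["E1"].d) == (2, 1, 1, 1)
        assert (tables["E2"].a, tables["E2"].b, tables["E2"].c,
                tables["E2"].d) == (1, 2, 0, 2)

    def test_duplicate_pt_counts_once(self):
        reports = self._reports()
        reports[1].reactions = ["E1", "E1"]
        tables = build_tables(reports, "X")
        assert tables["E1"].a == 2

    def test_only_target_events_tabulated(self):
        tables = build_tables(self._reports(), "X")
        assert set(tables) == {"E1", "E2", "E3"}

    def test_soc_level_requires_map(self):
        with pytest.raises(ConfigurationError):
            build_tables(self._reports(), "X", level="SOC")

    def test_soc_level_groups_pts(self, toy_meddra):
        reports = [
            make_report(report_id="1", case_id="1",
                        reactions=["Rash", "Stevens-Johnson syndrome"]),
            make_report(report_id="2", case_id="2", reactions=["Nausea"]),
        ]
        for r in reports:
            r.drugs[0].standardized_name = "sulfasalazine"
        tables = build_tables(reports, "sulfasalazine", level="SOC",
                              meddra=toy_meddra)
        # two PTs from the same SOC in one report count once
        assert tables["Skin and subcutaneous tissue disorders"].a == 1


class TestRor:
    def test_worked_example(self):
        ror, lo, hi = compute_ror(ContingencyTable(10, 90, 100, 9900))
        assert ror == pytest.approx(11.0)
        assert lo == pytest.approx(5.5595, abs=1e-3)
        assert lo <= ror <= hi

    def test_symmetric_table(self):
        assert compute_ror(ContingencyTable(25, 25, 25, 25)).ror == pytest.approx(1.0)

    def test_independence_gives_one(self):
        # any table with ad = bc
        assert compute_ror(ContingencyTable(4, 8, 20, 40)).ror == pytest.approx(1.0)

    def test_zero_cell_corrected(self):
        result = compute_ror(ContingencyTable(5, 10, 0, 100))
        assert math.isfinite(result.ror)
        # equals the +0.5-corrected odds ratio
        assert result.ror == pytest.approx((5.5 * 100.5) / (10.5 * 0.5))

    def test_zero_cell_sentinel_when_correction_disabled(self):
        result = compute_ror(ContingencyTable(0, 10, 5, 100),
                             zero_correction=False)
        assert math.isnan(result.ror)


class TestPrrChi2:
    def test_worked_example(self):
        prr, chi2 = compute_prr_chi2(ContingencyTable(10, 90, 100, 9900))
        assert prr == pytest.approx(10.0)
        assert chi2 == pytest.approx(74.45, abs=0.01)

    def test_independence(self):
        prr, chi2 = compute_prr_chi2(ContingencyTable(25, 25, 25, 25))
        assert prr == pytest.approx(1.0)
        assert chi2 == pytest.approx(0.0)

    def test_closed_form_matches_cellwise_oracle(self):
        rng = np.random.default_rng(42)
        for t in random_tables(rng, 200):
            closed = compute_prr_chi2(t).chi2
            assert closed == pytest.approx(chi2_cellwise(t), rel=1e-9)

    def test_yates_correction_reduces_chi2(self):
        t = ContingencyTable(10, 90, 100, 9900)
        assert compute_prr_chi2(t, yates=True).chi2 < compute_prr_chi2(t).chi2


class TestBcpnn:
    def test_symmetric_table_ic_is_exactly_zero(self):
        ic, ic025 = compute_bcpnn(ContingencyTable(25, 25, 25, 25))
        assert ic == 0.0
        assert ic025 == pytest.approx(-0.620, abs=1e-3)

    def test_zero_a_gives_negative_ic(self):
        ic, _ = compute_bcpnn(ContingencyTable(0, 50, 50, 900))
        assert ic < 0

    def test_closed_form_matches_monte_carlo(self):
        rng = np.random.default_rng(7)
        for t in list(random_tables(rng, 8, a_min=20)):
            draws = sample_bcpnn_ic(t, n_draws=100_000,
                                    rng=np.random.default_rng(1))
            ic, _ = compute_bcpnn(t)
            assert ic == pytest.approx(float(draws.mean()), abs=0.05)

    def test_priors_must_be_positive(self):
        with pytest.raises(ValueError):
            BCPNNPriors(gamma11=0)


class TestEbgmSimplified:
    def test_worked_example(self):
        ebgm, ebgm05 = compute_ebgm_simplified(ContingencyTable(10, 90, 100, 9900))
        assert ebgm == pytest.approx(101000 / 11000)
        assert ebgm05 == pytest.approx(5.1785, abs=1e-3)

    def test_observed_equals_expected(self):
        ebgm, _ = compute_ebgm_simplified(ContingencyTable(25, 25, 25, 25))
        assert ebgm == pytest.approx(1.0)


class TestMgps:
    def test_single_component_conjugacy_exact(self):
        prior = MGPSPrior(alpha1=2.0, beta1=4.0, alpha2=2.0, beta2=4.0, p=1.0)
        a, e = 7, 3.2
        assert mgps_posterior_mean(a, e, prior) == pytest.approx(
            (2.0 + a) / (4.0 + e), rel=1e-12
        )
        ebgm, _ = compute_ebgm_mgps(ContingencyTable(7, 93, 250, 9650), prior)
        t = ContingencyTable(7, 93, 250, 9650)
        expected = math.exp(special.digamma(2.0 + t.a) - math.log(4.0 + t.expected))
        assert ebgm == pytest.approx(expected, rel=1e-9)

    def test_ebgm05_is_fifth_posterior_percentile(self):
        prior = MGPSPrior(alpha1=0.5, beta1=0.2, alpha2=3.0, beta2=3.0, p=0.4)
        t = ContingencyTable(12, 88, 300, 9600)
        _, ebgm05 = compute_ebgm_mgps(t, prior)
        w, shapes, rates = mgps_posterior(t.a, t.expected, prior)
        cdf = float(np.sum(w * stats.gamma.cdf(ebgm05, shapes, scale=1 / rates)))
        assert cdf == pytest.approx(0.05, abs=1e-6)

    def test_likelihood_dominates_for_large_counts(self):
        prior = MGPSPrior(alpha1=2.0, beta1=4.0, alpha2=1.0, beta2=1.0, p=0.5)
        a, e = 100_000, 20_000.0
        t_ebgm = math.exp(
            special.digamma(prior.alpha1 + a) - math.log(prior.beta1 + e)
        )
        assert t_ebgm == pytest.approx(a / e, rel=0.01)
        w, shapes, rates = mgps_posterior(a, e, prior)
        ebgm = math.exp(float(np.sum(w * (special.digamma(shapes) - np.log(rates)))))
        assert ebgm == pytest.approx(a / e, rel=0.01)

    def test_fit_recovers_single_gamma_population(self):
        # cells simulated with lambda ~ Gamma(shape 2, rate 4)
        rng = np.random.default_rng(3)
        n_cells = 500
        e = rng.uniform(0.5, 50.0, size=n_cells)
        lam = rng.gamma(2.0, 1.0 / 4.0, size=n_cells)
        a = rng.poisson(lam * e)
        prior = fit_mgps((a, e))
        conjugate = (2.0 + a) / (4.0 + e)
        fitted = np.array(
            [mgps_posterior_mean(ai, ei, prior) for ai, ei in zip(a, e)]
        )
        within = np.abs(fitted / conjugate - 1.0) < 0.10
        assert within.mean() >= 0.95

    def test_single_cell_is_an_error(self):
        with pytest.raises(ValueError):
            fit_mgps([ContingencyTable(3, 7, 10, 80)])

    def test_mixture_weight_bounds(self):
        with pytest.raises(ValueError):
            MGPSPrior(1, 1, 1, 1, p=0.0)


class TestInvariants:
    def test_independence_null_all_statistics(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            a, k1, k2 = (int(rng.integers(1, 30)) for _ in range(3))
            # ad = bc by construction
            t = ContingencyTable(a, a * k1, a * k2, a * k1 * k2)
            assert compute_ror(t).ror == pytest.approx(1.0)
            assert compute_prr_chi2(t).prr == pytest.approx(1.0)
            assert compute_prr_chi2(t).chi2 == pytest.approx(0.0, abs=1e-12)
            assert compute_ebgm_simplified(t)[0] == pytest.approx(1.0)

    def test_statistics_increase_with_a(self):
        """Monotonicity in the sparse-reporting regime (a << b, c, d).

        ROR and PRR are increasing in a for any table; the raw
        observed/expected ratio is only increasing while the target
        pair remains rare relative to its margins, which is the regime
        spontaneous-report tables live in.
        """
        rng = np.random.default_rng(6)
        for _ in range(50):
            t = ContingencyTable(
                a=int(rng.integers(1, 30)),
                b=int(rng.integers(500, 2000)),
                c=int(rng.integers(500, 2000)),
                d=int(rng.integers(10000, 50000)),
            )
            t2 = ContingencyTable(t.a + 1, t.b, t.c, t.d)
            assert compute_ror(t2).ror > compute_ror(t).ror
            assert compute_prr_chi2(t2).prr > compute_prr_chi2(t).prr
            assert compute_bcpnn(t2)[0] > compute_bcpnn(t)[0]
            assert compute_ebgm_simplified(t2)[0] > compute_ebgm_simplified(t)[0]


class TestCriteriaAndRanking:
    def _result(self, **overrides):
        base = dict(a=5, b=95, c=100, d=9800, ror=2.0, ror_ci95_low=1.2,
                    ror_ci95_high=3.5, prr=2.5, chi2=5.1, ic=0.5, ic025=0.1,
                    ebgm=2.4, ebgm05=2.1)
        base.update(overrides)
        t = ContingencyTable(base["a"], base["b"], base["c"], base["d"])
        result = evaluate_table("E", t)
        for key, value in base.items():
            if key not in ("a", "b", "c", "d"):
                setattr(result, key, value)
        return result

    def test_all_four_positive(self):
        (r,) = apply_criteria([self._result()], CriteriaConfig())
        assert r.ror_positive and r.prr_positive
        assert r.bcpnn_positive and r.ebgm_positive
        assert r.overall_positive

    def test_min_reports_gates_ror_and_prr(self):
        (r,) = apply_criteria([self._result(a=2)], CriteriaConfig())
        assert not r.ror_positive and not r.prr_positive
        assert r.bcpnn_positive  # count threshold applies to ROR/PRR only

    def test_ic025_boundary_is_strict(self):
        (r,) = apply_criteria([self._result(ic025=0.0)], CriteriaConfig())
        assert not r.bcpnn_positive

    def test_evans_preset_raises_prr_bar(self):
        (r,) = apply_criteria([self._result(prr=1.5)],
                              CriteriaConfig.evans2001())
        assert not r.prr_positive

    def test_combine_rule_subset(self):
        cfg = CriteriaConfig(combine_rule=("ror", "prr"))
        (r,) = apply_criteria([self._result(ebgm05=1.0)], cfg)
        assert r.overall_positive

    def test_rank_order_and_ties(self):
        results = [
            self._result(ror=5.0), self._result(ror=9.0),
            self._result(ror=2.0),
        ]
        results[0].event, results[1].event, results[2].event = "A", "B", "C"
        apply_criteria(results)
        top = rank_top_k(results, 2)
        assert [r.event for r in top] == ["B", "A"]
        # tie on ROR broken by larger a
        tied = [self._result(ror=5.0, a=5), self._result(ror=5.0, a=50, b=50)]
        tied[0].event, tied[1].event = "low_a", "high_a"
        apply_criteria(tied)
        assert [r.event for r in rank_top_k(tied, 2)][0] == "high_a"

    def test_k_edge_cases(self):
        results = apply_criteria([self._result()])
        assert rank_top_k(results, 0) == []
        assert len(rank_top_k(results, 99)) == 1
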