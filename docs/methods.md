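# Methods

This note documents the statistical model behind `pvsignal`, the choices
made where several defensible options exist, and what the synthetic-data
experiments do and do not demonstrate.

## The data model

A spontaneous reporting system is a collection of *cases*; each case may
be submitted several times as revised *report versions*. A report
carries demographics (often missing), one or more drug entries with a
role code (Primary Suspect PS, Secondary Suspect SS, Concomitant C,
Interacting I), reactions coded as MedDRA Preferred Terms (PTs), outcome
codes (DE, LT, HO, DS, CA, RI, OT), and per-drug indications. Quarterly
extracts come in two layouts: legacy files (through 2012Q3) keyed by ISR
with no explicit case version, and current files keyed by
PRIMARYID/CASEID with a CASEVERSION column. `pvsignal` reads both,
detecting the dialect from the header.

Curation before any counting:

1. **Deduplication** keeps one report per case id: the highest case
   version, ties broken by latest receipt date, then largest numeric
   report id. Legacy files have no version column, so every legacy
   record carries version 0 and the date/id tie-breaks do the work.
   Deduplication is idempotent and reports without a case id pass
   through as singletons.
2. **Drug-name standardization** replaces free-text NLP with a
   deterministic normalizer (case-fold; punctuation to spaces; drop
   dose tokens such as `500 MG`/`500mg` and pharmaceutical-form tokens)
   followed by lookup in a user-supplied synonym dictionary
   (raw name → ingredient). Unmapped names fall back to their
   normalized form and are counted.
3. **PS filtering** defines the exposed set as reports in which the
   target drug appears with role PS. The comparison background is the
   *whole* curated database, including reports where the target drug
   appears in non-PS roles — excluding them is a defensible alternative
   but is not what a whole-database comparator means.
4. Reports with no reactions after curation contribute to no cell and
   are dropped (counted in the manifest).

Counting is report-level throughout: a PT repeated within one report
counts once, and at SOC level two PTs from the same SOC in one report
count once.

## The four estimators

With a, b, c, d as in the README table and N = a+b+c+d:

- **ROR** (reporting odds ratio): ad/bc, CI
  `exp(ln ROR ± z·sqrt(1/a + 1/b + 1/c + 1/d))`, z = 1.96.
- **PRR**: `[a/(a+b)] / [c/(c+d)]`; χ² is the Pearson statistic of the
  table, `N(ad−bc)² / ((a+b)(c+d)(a+c)(b+d))`, without continuity
  correction by default (Yates optional). The default PRR magnitude
  threshold is 0 — i.e., the decision is carried by χ² > 4 and the
  count floor — with the conventional PRR ≥ 2 rule available as the
  `evans2001` preset.
- **BCPNN IC**: the information component under independent Beta
  posteriors for P(drug, event), P(drug) and P(event), with the joint
  prior pseudo-denominator γ calibrated from the margins so that IC = 0
  under exact independence:

      γ = γ11 (N+α)(N+β) / ((a+b+α1)(a+c+β1))
      IC = log2 [ (a+γ11)(N+α)(N+β) / ((N+γ)(a+b+α1)(a+c+β1)) ]

  with defaults γ11 = α1 = β1 = 1, α = β = 2. IC025 = IC − z·sqrt(V)
  uses the standard closed-form variance approximation; z defaults to
  1.96 (2.0 is a common alternative convention and is configurable).
  The symmetric table (25,25,25,25) gives IC = 0 exactly — an integer
  identity (26·102·102 = 104·51·51) that the tests assert.
- **EBGM**: the default "simplified" mode is the raw relative reporting
  ratio aN/((a+b)(a+c)) with EBGM05 = exp(ln EBGM − 1.645·se) on the
  same log-scale standard error — the common FAERS-mining practice. The
  opt-in MGPS mode fits DuMouchel's two-component gamma-mixture prior
  on the relative reporting ratio by marginal maximum likelihood over
  all (drug, event) cells (each component marginal is negative
  binomial; Nelder–Mead from the classic start (0.2, 0.1, 2, 4, 1/3)),
  then reports the posterior geometric mean
  `exp(Σ w_k (ψ(α_k+a) − ln(β_k+E)))` and the exact 5th posterior
  percentile by root-finding on the mixture CDF. With a single
  component this reduces to gamma-Poisson conjugacy exactly, which the
  tests check to 1e-9.

**Zero cells.** Ratio estimators are undefined on zero cells; when any
cell is 0 the Haldane–Anscombe +0.5 correction is applied to all four
cells and the result is flagged `corrected` (disable it and degenerate
tables return NaN sentinels). BCPNN needs no correction — its priors
regularize. In practice flagged events all have a ≥ 3 anyway.

**Positive-signal criteria.** Defaults: ROR CI low > 1 and a ≥ 3;
PRR > 0, χ² > 4 and a ≥ 3; IC025 > 0; EBGM05 > 2. All inequalities are
strict. The overall flag is the four-way AND by default ("a signal by
every algorithm"); `any` or a named subset are configurable. Ranking
filters to overall-positive, sorts by ROR (configurable) descending,
ties broken by a descending then label ascending.

**A non-obvious caveat**: the simplified EBGM is *not* monotone in a
with b, c, d fixed — adding target-drug-event reports also grows N and
both margins, and once a is comparable to its margins the
observed/expected ratio turns over. It is strictly increasing in the
sparse-reporting regime (a ≪ b, c, d) that real SRS tables occupy, and
that is the regime in which the property is tested.

## The synthetic reporting system

The generator defines the study conditions under which the pipeline's
operating characteristics are measured:

- Each report draws one PS drug from `drug_weights` (default: a seeded
  symmetric-Dirichlet draw) and 0–2 concomitant drugs; its reaction
  count is truncated-geometric (mean 1.8, max 10) and the PTs are drawn
  without replacement from `q_d(e) ∝ event_weights(e)·λ(d,e)` — λ = 1
  everywhere except injected (drug, event) pairs.
- Demographics are drawn independently of drug/event assignment. The
  categorical defaults pin the published descriptive shares where a
  reference study states them (female 68.06%, male 26.41%; ages 45–65
  at 35.03%; physician reporters 38.39%; rheumatoid-arthritis
  indication 33.49%; outcome shares OT 51.95, HO 32.13, LT 6.06,
  DS 4.55, DE 4.00, CA 1.00, RI 0.31) and fill the remaining categories
  once with realistic values (e.g., `<18` 5%, `18–45` 30%, `≥65` 20%,
  unknown 9.97%; country mass concentrated in US/CA/JP/GB). By default
  a report carries at most one outcome record: drawing several without
  replacement would bias record-level category shares away from the
  configured ones (the model still supports multi-outcome reports, and
  curation/descriptives handle them).
- A configurable fraction of cases is re-emitted as 2–3 versions with
  redrawn raw drug spellings; the intended final version per case is
  the returned ground truth. In the legacy dialect all versions carry
  case version 0 and are ordered by receipt date and report id, exactly
  as legacy deduplication must resolve them.
- Fixed seed ⇒ byte-identical files (integer-state PRNG, no
  locale-dependent formatting). Age bins are half-open,
  lower-inclusive: [0,18), [18,45), [45,65), [65,∞).

What the generator does *not* emulate: reporting delays and
time-stratified backgrounds, demographic confounding (demographics are
independent of drug and event), masking/competition bias, multi-
ingredient products, and free-text coding noise beyond the variant
table. Passing recovery tests therefore show the estimators and the
curation chain are correct under the stated model — not that real FAERS
signals at these thresholds are causal.

## Design of the seeded experiments

**Injected-risk bias.** Injecting λ on one pair and renormalizing the
per-draw event distribution makes the per-draw probability
λw/(1 + w(λ−1)), so the report-level risk ratio is biased low by the
factor 1 + w(λ−1). With ~200 events (w ≈ 0.005) this bias is ≤ 4.5% at
λ = 10, well inside the Woolf CI half-width at the counts used. A
second, larger effect concerns the observed/expected ratio: a signal on
a *common* drug inflates the event margin a+c, so EBGM ≈
λ/(1 + p_d(λ−1)) where p_d is the drug's share of the database. The ROR,
an odds ratio, is insensitive to this.

The experiment designs follow from that analysis (chosen up front, not
adjusted to outcomes):

- **ROR coverage** (100 seeded replicates per λ ∈ {2, 5, 10}): 6,000
  reports, 4 drugs with weight 0.25 each, 200 uniform events — expected
  a ranges from ~26 (λ=2) to ~130 (λ=10), and the CI covers the injected
  λ in ≥ 85/100 replicates.
- **EBGM recovery** (median over seeds within 15% of λ): requires a
  *rare* target drug, so it runs at 30,000 reports with target weight
  0.02 (expected a ≈ 26, margin-inflation factor 1.08).
- **Null calibration** (20 seeded replicates): 5,000 reports, 8 drugs,
  100 events, uniform weights, no signals; among pairs with expected
  count ≥ 3 the four-way AND criterion flags well under 5% (in practice
  ~0% — EBGM05 > 2 is essentially never met under the null).
- **BCPNN closed form vs Monte Carlo** (50 tables, 1e5 draws from the
  three independent Beta posteriors): agreement within 0.05 on IC and
  V(IC). The closed form is a log of posterior means while the MC mean
  is a mean of logs; they differ by ≈ 1/(2a·ln 2) bits, so the
  comparison uses tables with a ≥ 20 where that analytic gap is below
  the tolerance. This is a property of the estimator's definition, not
  an implementation error.

Problem sizes above are also the ones `scripts/acceptance.py` and the
test suite run.

## Numerical choices and degenerate inputs

- Ages are converted to years with divisors DEC×10, MON÷12, WK÷52.143,
  DY÷365.25, HR÷8766; values outside [0, 150) become missing.
- Input files are decoded as Latin-1 with replacement (real extracts
  contain non-UTF-8 bytes); the encoding is a parameter.
- MGPS optimization runs on log/logit-transformed parameters;
  non-convergence warns and returns the best point found, flagged. The
  EBGM05 root-find uses Brent's method bracketed by the component 5th
  percentiles (the mixture quantile must lie between them), to an
  absolute tolerance that keeps |CDF − 0.05| < 1e-6.
- Empty descriptive inputs yield empty tables with denominator 0; an
  empty target-drug set is a distinct pipeline error (CLI exit code 3),
  not an empty file.
- Output CSVs render floats with 4 decimals, fixed column order, rows
  in rank order; reruns on the same inputs are byte-identical.

## Known limitations

No multiple-comparison control is applied (none is conventional in this
kind of screening; the four-way AND is itself conservative). Statistics
are unstratified — no age/sex/time stratification of expected counts.
The synonym normalizer is deliberately simple and will not split
multi-ingredient products. SOC attribution requires the user's PT→SOC
table; PTs missing from it are reported under an `UNMAPPED` sentinel
rather than silently dropped.
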