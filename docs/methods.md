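# Methods

## Data model

The analysis presupposes a record-level database even though public
front-ends to spontaneous reporting systems expose only aggregates. The
canonical schema here is a long line list (one row per report–drug–event
triple) merged by `report_id` into reports carrying a set of drug codes, a
set of event PTs, and report-level demographics (sex; nine age bands from
0–27 days to ≥75 years; five continents; calendar year). "Unknown" is a
first-class stratum on every axis because report summaries tabulate it.
Codes are matched case-sensitively after whitespace trimming (controlled
vocabulary). Each PT resolves to exactly one primary SOC through a
two-column hierarchy file; PTs that do not resolve are collected and
reported, never dropped.

## Contingency tables

Counting is report-level: a report contributes at most 1 to any cell even
when it carries several qualifying PTs, because the distribution theory of
ROR/PRR treats reports, not occurrences, as the sampling unit. The
comparator is all other reports in the supplied database, which makes the
background explicit and configurable (restrict the database to restrict
the comparator). A report listing several drugs attributes its events to
every drug on the report. SOC-level tables count reports with ≥1 PT in the
SOC. No stratified or adjusted tables are produced; all statistics are
crude univariate disproportionalities.

## Statistics

With E = (a+b)(a+c)/N:

- ROR and its Woolf CI; PRR and its log-scale CI with variance
  1/a − 1/(a+b) + 1/c − 1/(c+d). Undefined configurations (zero cells
  where a formula needs support) propagate as NaN markers and always flag
  negative at screening; an optional Haldane +0.5 correction exists but is
  off by default so that undefined results stay visible.
- Pearson chi-square without continuity correction by default. The
  no-correction choice is validated by the margin-reconstruction checks:
  the chi-square implied by published rows matches the printed values only
  without the correction. Yates' correction is available as a flag.
- IC defaults to the shrunk-ratio form log₂((a+s)/(E+s)), s = 0.5, with
  IC025 the base-2 log of the 2.5th percentile of a Gamma(a+s, rate E+s)
  posterior. Published tables sometimes print IC = log₂(EBGM) instead;
  that variant is provided as the `log2_ebgm` mode. Printed IC025 columns
  in the literature follow several incompatible conventions, so no single
  default can reproduce all of them; the gamma-quantile default is the one
  with an exact posterior interpretation.
- EBGM follows the gamma–Poisson shrinker: prior
  λ ~ w·Gamma(α₁,β₁) + (1−w)·Gamma(α₂,β₂), marginal likelihood a mixture
  of negative binomials, posterior again a gamma mixture with updated
  weights. EBGM = exp(Σⱼ Qⱼ(ψ(αⱼ+a) − ln(βⱼ+E))) and EBGM05 solves the
  posterior mixture CDF = 0.05 by bracketed Brent root-finding between the
  component quantiles (bracket padded geometrically; a component with
  posterior weight below 1e−12 short-circuits to the other component's
  quantile).

### Prior fitting

Hyperparameters are fitted by maximising the summed negative-binomial
mixture log-likelihood over all (a, E) cells of the database, starting
from the canonical (0.2, 0.1, 2, 4, 1/3). Parameters are optimised on the
log/logit scale with a derivative-free bounded Powell search (box
|θ| ≤ 13.8, i.e. e^±13.8 on the natural scale; ftol 1e−6). The box
matters for degenerate inputs: a database whose pairs are all exactly null
has its likelihood maximised by a point-mass prior at λ = 1, and an
unbounded simplex search drifts indefinitely toward that boundary, while
the bounded search terminates there cleanly. Non-convergence raises an
error carrying the best-so-far parameters and the optimiser trace. At
5·10⁴ simulated cells the fit recovers all five canonical hyperparameters
within a few percent in ~10 s.

The mixture likelihood is invariant under component relabeling, so tests
that compare fitted to generating parameters match components by weight.

### A note on shrinkage bounds

The posterior *arithmetic* mean under a single gamma component,
(α+a)/(β+E), always lies between the raw ratio a/E and the prior mean
α/β. Neither the posterior geometric mean (EBGM) nor the two-component
posterior mean inherits this interval property: the geometric mean sits
strictly below the arithmetic mean (ψ(x) < ln x), and mixture-weight
updating can move the posterior mean outside the window spanned by a/E
and the prior mixture mean. The property tests therefore assert what is
actually a theorem — EBGM05 < EBGM < posterior mean, monotonicity of EBGM
and IC in a at fixed E, and the single-component interval bound.

## Screening

Default thresholds: a ≥ 3; ROR ≥ 1 and ROR CI lower bound > 1; PRR ≥ 2
and χ² ≥ 4; IC025 > 0; EBGM05 > 2. The count gate a ≥ 3 is part of the
ROR and PRR rules, so the joint flag is exactly the conjunction of the
four per-algorithm flags. The PRR auxiliary rule defaults to the
conjunctive "χ² ≥ 4" form used in published table footnotes; the
disjunctive "PRR CI lower bound > 1 or χ² ≥ 4" variant is selectable.
Tables rank by ROR point estimate (descending, ties by count then PT
code); ranking by the CI lower bound — a better measure of signal
strength — or by count is available. The label comparison partitions
joint-positive rows against a plain-text PT list representing the
product information.

### Margin reconstruction

For rows with a large comparator (c, d ≫ a+b) the Woolf variance
collapses to s² ≈ 1/a + 1/b, so a printed (n, ROR, ROR_low) row can be
inverted: b = 1/(s² − 1/a), ρ = d/c = ROR·b/a, and the implied chi-square
(aρ − b)²/[(a+b)ρ] and PRR a(1+ρ)/(a+b) follow. Rows whose printed CI is
tighter than the Poisson floor (s² ≤ 1/a) are rejected as internally
inconsistent. The inversion is exact up to the neglected 1/c + 1/d terms;
round-trip accuracy on synthetic tables is ≲0.5% when c exceeds the drug
margin by two orders of magnitude.

## Descriptive tables

Percentages print at 2 decimal places with half-up rounding. Demographic
axes are independent marginals of the drug's report set. SOC and PT
distributions default to the occurrence denominator (report–PT pairs),
under which SOC counts equal the sum of PT-level a within the SOC; the
distinct-report denominator is available and the denominator used is
always echoed in the output. Top-k PT tables rank by count, ties
alphabetical.

## Synthetic data

`generate_reports` draws, per report: one drug from `drug_freqs` (an
optional co-reported second drug with probability `extra_drug_prob`,
default 0 to keep comparator bookkeeping exact); an event count from a
truncated Poisson (λ = 1, conditioned ≥ 1, mean ≈ 1.58 events/report,
matching the ~1.5 occurrences-per-report ratio typical of such extracts);
and event PTs from the background frequency vector reweighted so
P(pt | drug) ∝ event_freqs[pt]·θ(drug, pt), where θ is the embedded
reporting-rate ratio (1 everywhere except declared signal pairs).
Demographics are drawn independently per axis; the default mix emulates a
large Asian-dominated extract with a middle-aged/elderly skew. The default
scenario (`default_config`) has 20 drugs and 200 PTs with Zipf-like
frequencies over 21 SOCs and three embedded signals (θ = 5, 10, 20).

What the generator does **not** emulate: under-reporting dynamics,
notoriety bias, time-varying reporting rates, demographic–event
correlation, and real-database overdispersion. The last point matters for
interpretation: null pairs here are exactly Poisson, so the fitted
empirical-Bayes prior is far tighter than priors fitted to real
spontaneous-report databases, and EBGM shrinks genuine embedded signals
aggressively (they still clear EBGM05 > 2 at the strengths tested).
Passing tests therefore demonstrate correctness of the machinery and
calibration under idealised reporting, not real-world operating
characteristics.

`generate_cells` draws (a, E) directly from the gamma–Poisson mixture
(E log-uniform on a configurable range, default 0.1–100) for
prior-recovery testing at exact model conditions.

## Problem sizes used in the test suite

Deterministic checks run on single tables. Stochastic checks use: prior
recovery at 5·10⁴ cells; Woolf CI coverage over 10⁴ binomial tables
(margins 2000/2000, true OR 1.714); null calibration on a 10⁵-report
database (20 drugs × 200 PTs, all θ = 1); power over 200 replicates of a
3 000-report, 8-drug × 40-PT database with one θ = 20 pair (realized
signal counts ≈ 100 ≫ 20). The whole suite runs in about two minutes on
one CPU.

## Known limitations

- No multiple-testing correction and no causality scoring; joint-positive
  rows are hypothesis-generating statistical associations only.
- IC025 printed by other software may follow a normal-approximation or
  MCMC convention and will not match the gamma-quantile default here.
- The prior fit assumes the supplied cells are exchangeable draws from one
  mixture; fitting on a database containing very strong signals biases the
  prior slightly upward (standard for MGPS-style analyses).
- z defaults to 1.96 (the 2-dp convention of published tables), not the
  exact 0.975 normal quantile; configurable.
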