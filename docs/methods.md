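# Methods

This note documents the statistical model, its assumptions, the numerical
conventions, and the design decisions behind `ecostatus`. It is written for
users who need to judge what an assessment run does — and does not — tell
them.

## Censored likelihoods

The unit of evidence is the probability that an indicator passes its target,
computed from the sampling distribution of its annual mean. Because the
assessment is pass/fail, the likelihood uses the distribution function (tail
mass), not the density:

* `normal` (default): `p = Φ((mean − S)/σ)` for higher-is-better, mirrored
  for lower-is-better. A mean exactly at the target S gives p = 0.5 under
  any symmetric distribution — no evidence either way.
* `lognormal`, for positive concentration-type indicators: the log value is
  treated as Normal(log mean, σ/mean); the delta-method coefficient of
  variation keeps p = 0.5 when the mean sits at the target.
* σ = 0 degenerates to a step: 1 strictly on the good side, 0 on the bad
  side, 0.5 at the target exactly.

**Precaution.** Precautionary target setting is a single scalar ≥ 0 in units
of the year's sampling SD: the effective target is shifted by
`precaution · σ` toward the bad side, so passing requires stronger evidence
(`precaution=1` at an at-target mean yields Φ(−1) ≈ 0.159). Default 0; the
scalar form was chosen because only the principle, not a formula, is
standard in the assessment literature.

**Clipping.** Before aggregation, likelihoods are clipped into
`[1e−9, 1 − 1e−9]`. Unclipped 0/1 values would absorb the sequential
posterior permanently at certainty after a single year, which no finite
monitoring series can justify.

## The two-state Bayes chain

GES and non-GES are exclusive, exhaustive hypotheses. With conditionally
independent indicators the year's likelihoods are
`L(data|GES) = ∏ᵢ pᵢ` and `L(data|non-GES) = ∏ᵢ (1 − pᵢ)` — the non-GES
product is forced by the two-state structure once the per-indicator evidence
is censored to pass/fail. The posterior is computed in log-odds,

    logit(posterior) = logit(prior) + Σᵢ logit(pᵢ),

which is algebraically identical to the product form but immune to underflow
for many indicators over many chained years (tests compare against the
literal product form at 1e−12). Consequences worth knowing:

* the update is symmetric in the indicators (permutation invariant) and
  strictly increasing in every pᵢ and in the prior;
* p = 0.5 indicators contribute nothing; an indicator missing in a year is
  therefore treated as exactly no evidence (and logged) in union-years mode;
* the assessment default uses the intersection of years available in every
  series.

**Prior chaining.** Year t's posterior is year t+1's prior; the initial
prior defaults to the uninformative 0.5 (published worked examples use 0.45,
0.55 or 0.01 — these are run configuration, not defaults). The chain is what
makes the index trend-sensitive and robust to single-year noise; it also
means a bad early history suppresses the index long after conditions
improve (see the README example). An optional discount
`prior ← λ·posterior + (1−λ)·0.5` (default λ = 1, i.e. off) relaxes the
memory; it is provided for sensitivity analysis, not used by default.

The chained prior is additionally clipped inside (0, 1) so that a long run
of near-certain evidence cannot round the prior to exactly 0 or 1 in
floating point.

**At-target chains.** Two indicators exactly at target under a 45% prior
hold the posterior at 45.0% in every year. The published table of the
corresponding simulation prints 45.1% in the second year; the exact
at-target construction cannot produce movement (neutral evidence is a fixed
point), so the package reproduces 45.0% and records the 0.1-point
discrepancy — presumably the original appendix data sat marginally off
target — rather than adjusting anything to match.

**Early warning.** For each indicator, maximal runs of ≥ k consecutive
years with p < threshold (or p > 1 − threshold) are flagged with their year
span and mean likelihood. Defaults threshold = 0.25, k = 3: roughly "one
sampling SD off target, three assessments running". Both are configurable;
no canonical values exist.

## Alternative aggregations

For method comparison the package also computes: the one-out-all-out verdict
(pass only if every mean is on the good side) together with its joint pass
probability ∏pᵢ; the type-II-error curve `p_each^n`; and weight-normalized
additive utility `Σwᵢuᵢ/Σwᵢ` (the Bayesian index itself applies no weights).
Normalization transforms (z-score with the n−1 sample SD, ecological quality
ratio x/reference, range scaling) report pre/post diagnostics because each
manufactures new data properties — z-scoring erases scale differences
between series entirely, EQR moves data to ratio scale, range compresses
toward uniform.

## Indicator space: ordination and selection

* **PCA** is always of the correlation matrix (z-scored columns): indicator
  units are incommensurable, so covariance PCA would be meaningless.
  Variance shares are eigenvalues over their sum; a constant column is an
  error naming the indicator.
* **RDA** regresses the z-scored response columns (all columns except the
  constraints) on the constraint columns by least squares and reports
  `constrained_share` = fitted variance / response variance; the constrained
  axes are the PCA of the fitted values. Excluding the constraints from the
  response side avoids self-explanation inflating the share.
* Two accountings are deliberately distinguished. The response-relative
  `constrained_share` answers "how well do the selected indicators predict
  the rest of the indicator space?" but is *not* monotone as constraints are
  added (moving a well-predicted column from the response side to the
  constraint side can lower the response average). Selection therefore
  tracks the inclusive `explained_share` =
  (k·(n−1) + fitted SS)/((n−1)·p) over all p columns, counting each
  selected indicator as fully self-represented. This share is provably
  monotone non-decreasing, reaches 1 when all columns are selected, and
  gives exactly zero marginal gain for a duplicated column — the properties
  a selection trajectory needs. Its complement is the unexplained-variance
  error term attached to the assessment report.
* **Greedy forward selection** adds, at each step, the indicator maximizing
  the inclusive share; ties break toward the earlier column (documented,
  deterministic). Exhaustive subset search is available up to 12 columns as
  a certificate. Note the attenuation effect: a single noisy proxy of a
  latent factor explains roughly the *square* of the factor's
  eigen-share in each sibling column, so the first selected indicator's
  share is below the factor share itself — this is correct regression
  behaviour, not a selection failure.
* **Partial correlations** come from the precision matrix of the correlation
  matrix (`r_ij = −P_ij/√(P_ii P_jj)`); with fewer years than indicators a
  Ledoit-Wolf shrinkage estimate replaces the singular sample matrix and the
  result is marked regularized. Pairs with |r| above the threshold
  (default 0.5) are flagged as conditionally dependent — evidence that the
  independence assumption of the likelihood product is strained.
* Matrix gaps are linearly interpolated per column strictly inside the
  observed span; rows still incomplete are dropped with a warning. No
  extrapolation.

## Synthetic ensembles

The generator produces `X[t,i] = Σ_f l_{if}·F_f[t] + baseline_i + trend_i·t
+ e_{it}` with unit-variance Gaussian factors (optionally AR(1) with unit
marginal variance) and noise scaled so each column's stationary variance is
1; the reported sampling SD (`obs_sd`) is a separate parameter, as in real
monitoring the interannual variability and the within-year sampling error
are different things. Factor strength is parameterized as the population
leading-eigenvalue share of the correlation matrix: a block of k equally
loading columns out of p has leading eigenvalue 1 + (k−1)l², so
`l² = (s·p − 1)/(k − 1)`. This is exactly the quantity correlation PCA
estimates, making parameter recovery a meaningful test (recovered within
±0.05 at 200 years in the suite).

Named scenarios (each fully parameterized, seeded, deterministic):

* `gradual_approach` — two indicators climb from their targets at 0.25
  sampling-SD/year over 10 years (interannual noise SD 0.05): the chained
  posterior must rise monotonically. The climb starts *at* the target
  because any year spent below it correctly drives the posterior down — a
  recovery from far below looks like the README example instead.
* `variable_ges` — two indicators fluctuate about their targets with
  interannual SD 6% of the sampling SD over 8 years. The log-odds chain is
  then a near-driftless random walk with total SD ≈ 1.7·0.06·√16 ≈ 0.4,
  so the posterior stays within (0.35, 0.65) for most seeds — the
  variability-buffering regime the scenario exists to represent.
* `early_warning` — as above plus one indicator pinned 1.5 sampling-SDs
  below target: its likelihood sits near Φ(−1.5) ≈ 0.07 every year, the
  run-scan flags exactly that indicator, and the aggregate declines.
* `southern_north_sea_like` — 36 indicators over 30 years: a dominant
  shared factor at 44% share loading on 24 series and a river-load factor
  at 13% loading on the other 12, emulating the correlation structure of a
  real regional indicator space. Greedy selection picks one indicator from
  each block first.

What the generator does **not** emulate: non-Gaussian and skewed indicator
distributions, serially correlated observation errors, irregular monitoring
gaps, regime shifts, and pressure–state causal structure. Tests passing on
these ensembles show the machinery is correct under its own assumptions;
they do not validate the independence or normality assumptions on any real
data set.

## Problem sizes and determinism

Test and acceptance computations use two-indicator chains for the analytic
worked-example checks (closed-form, instant), 10×6 matrices for ordination
oracles, 200-year ensembles for parameter recovery, and 100-seed Monte
Carlo for the buffering property — sizes at which the checked quantities
are stable to well inside their tolerances. All randomness flows through
seeded `numpy` generators; identical configuration and seed give
byte-identical JSON reports. The report schema ships in
`docs/schemas/assessment_report.schema.json` (generated from the pydantic
model that also validates reports on read).

## Known limitations

* Conditional independence of indicator evidence is assumed, screened for,
  but not enforced; strongly redundant indicators double-count evidence.
* The two-state formulation cannot express "partly good" descriptors; the
  posterior is a probability of a binary state, not a quality gradient.
* Percentile targets are descriptive, not normative: they encode "better
  than the observed past", nothing more.
* The ppDDE-style proxy target (converted from a related substance's
  target) must be supplied by the user; no conversion chemistry is built in.
* The explained-variance share attached to an assessment describes the
  indicator space the matrix covers, not the ecosystem; unmonitored
  processes are invisible to both.
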