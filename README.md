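# ecostatus

Probabilistic, trend-sensitive assessment of ecosystem health from indicator
time series.

Marine policy frameworks (the EU Marine Strategy Framework Directive, the
regional OSPAR/HELCOM assessments) ask a deceptively simple question: given a
few dozen monitored indicators — contaminant burdens, fish-community metrics,
breeding success — is the ecosystem in *Good Environmental Status* (GES)?
The common answers are unsatisfying: the exclusive one-out-all-out rule fails
the whole system whenever any single indicator fails (its probability of
confirming a genuinely good state is only ∏ᵢ pᵢ, collapsing as indicators are
added), while additive scoring needs weights and normalizations that
manufacture new data properties.

`ecostatus` implements an alternative for analysts of indicator-based
ecosystem assessments: a single Bayesian probability of GES, aggregated from
censored per-indicator likelihoods and chained through time.

## The model

Each indicator *Xᵢ* is observed as an annual mean with sampling SD and has a
target *S* with a direction of "good". Because the assessment question is
pass/fail (censored), indicator *i*'s likelihood of GES in year *t* is the
cumulative probability mass on the good side of the target,

  p_{i,t} = P(Xᵢ passes S) = Φ((x_{i,t} − S)/σ_{i,t}),

so a mean exactly at target contributes the neutral 0.5. Treating GES and
non-GES as the two exclusive states, the year's evidence combines as

  P(GES | data) = (∏ᵢ p_{i,t}) · prior / [(∏ᵢ p_{i,t}) · prior + (∏ᵢ (1 − p_{i,t})) · (1 − prior)],

and each year's posterior becomes the next year's prior. The chain remembers
the former state: it buffers single-year variability, responds to persistent
trends, and an indicator that consistently under- or over-scores while the
aggregate stays moderate raises an early-warning flag.

Around that core the package provides:

* **target setting** — percentile-based or fixed targets, plus precautionary
  target shifting (in sampling-SD units) inside the likelihood;
* **alternative aggregations** for comparison — one-out-all-out verdicts with
  their joint pass probability, the type-II-error curve p. vs. n, weighted
  additive utility, and normalization transforms (z-score, ecological quality
  ratio, range) with diagnostics of the properties they change;
* **a posteriori indicator selection** — correlation-matrix PCA of the
  indicator space, redundancy analysis (RDA) quantifying how much ecosystem
  variability a candidate subset explains, greedy forward selection, and a
  partial-correlation screen for the conditional-independence assumption;
* **a synthetic-data generator** reproducing the latent-factor structure of
  real regional indicator spaces (a dominant shared factor plus a secondary
  river-load factor), so every method is testable against known truth.

Everything is exposed both as scikit-learn-style estimators
(`GESBayesAssessor`, `CorrelationPCA`, `RedundancyAnalysis`,
`GreedyIndicatorSelector`, `PartialCorrelationScreen`) and as plain
functions, with an `ecostatus` command-line interface on top.

## Worked example

Two indicators approach their targets from the bad side — a large-fish
indicator (LFI, higher is better, target 0.485) and a contaminant in bird
eggs (ppDDE, lower is better, target 100 µg/kg):

```python
from ecostatus import AggregationConfig, IndicatorSet, assess, build_series

lfi = build_series(
    "LFI", times=[2005, 2006, 2007, 2008],
    means=[0.47, 0.48, 0.49, 0.50], sds=0.04,
    direction="higher_is_better", target=0.485, unit="proportion",
)
dde = build_series(
    "ppDDE", times=[2005, 2006, 2007, 2008],
    means=[112.0, 104.0, 97.0, 90.0], sds=15.0,
    direction="lower_is_better", target=100.0, unit="ug/kg",
)
a = assess(IndicatorSet((lfi, dde)), AggregationConfig(prior0=0.5))
for year, prior, post, row in zip(a.times, a.prior_chain, a.posterior, a.likelihoods):
    print(f"{year}: p_LFI={row[0]:.3f}  p_ppDDE={row[1]:.3f}  "
          f"prior={prior:.3f}  P(GES)={100*post:.1f}%")
```

```
2005: p_LFI=0.354  p_ppDDE=0.212  prior=0.500  P(GES)=12.8%
2006: p_LFI=0.450  p_ppDDE=0.395  prior=0.128  P(GES)=7.3%
2007: p_LFI=0.550  p_ppDDE=0.579  prior=0.073  P(GES)=11.7%
2008: p_LFI=0.646  p_ppDDE=0.748  prior=0.117  P(GES)=41.7%
```

Reading the output: in 2005 both means sit on the bad side of their targets,
so both pass probabilities are below 0.5 and the posterior drops far below
the uninformative 50% prior. As the means cross their targets (2007–2008 the
pass probabilities exceed 0.5) the posterior recovers — but only to 41.7%,
because the chained prior still remembers the poor start. A memoryless assessment of 2008 alone (`GESBayesAssessor(chain=False)`)
would instead report 84.4%; the gap is the trend memory.

The same pipeline runs from the shell against CSV inputs:

```sh
ecostatus simulate --scenario southern_north_sea_like --seed 1 --out data/
ecostatus select --matrix data/southern_north_sea_like_matrix.csv --k-max 2
ecostatus assess --config run.yaml
```

`select` reports which two indicators best span the 36-series indicator
space and the share of total variability they explain (whose complement is
the assessment's unexplained-information error term); `assess` writes a JSON
report (posterior trajectory, likelihood matrix, prior chain, warnings —
schema in `docs/schemas/`) plus a plain-text summary.

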