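# patenttrends

Tools for detecting shifts in commercial interest in traded wildlife from
patent-filing time series. Businesses that trade wildlife-derived products
(bear bile, pangolin scales, rhinoceros horn, sturgeon caviar, horseshoe-crab
blood, caterpillar fungus, ...) file patents to protect their innovations,
and the monthly rate and thematic content of those filings are an early
signal of market shifts — new product types, farming or synthetic
alternatives, responses to trade bans. `patenttrends` turns a corpus of
patent records (title, abstract, priority date, jurisdiction) into:

- **monthly filing-count series** per taxon, after include/NOT-exclude
  keyword filtering that removes confounders (e.g. *pangolin* is also the
  name of a *Drosophila* gene, so records mentioning *drosophila* are
  excluded) and deduplication;
- **Bayesian changepoint inference** on each series: counts are negative
  binomial in the NB2 mean/dispersion form, `y_t ~ NB2(μ_e, φ_e)` before an
  unknown month τ and `NB2(μ_l, φ_l)` from τ on, with exponential priors on
  the four parameters and a discrete-uniform prior on τ. The output is the
  full posterior `P(τ | y)` — the "probability of changepoint" per month —
  with MCMC diagnostics (split R-hat, effective sample size), an exact
  quadrature oracle for validation, and optional recursive segmentation for
  multiple shifts;
- **LDA topic modelling** of abstracts by collapsed Gibbs sampling, with
  topic-number selection balancing UMass semantic coherence against topic
  exclusivity;
- **codebook-based thematic coding**: topic labels (medicine, food, farming,
  synthetics, detection, ...) seeded from LDA top terms plus standard terms,
  applied multi-label and expanded iteratively until every patent carries at
  least one label, plus Fig-style cumulative label-proportion series;
- **trend statistics**: January–December year-on-year percentage changes
  (skipping years after a zero-filing year), mean percentage change, period
  medians, peak months, smoothed display series.

Since real patent scrapes cannot be redistributed, the package ships a
first-class synthetic-data generator (`patenttrends.simulate`) that plants
known changepoints, topic mixtures, taxon keywords and decoy terms, so the
whole pipeline is testable end to end against ground truth.

## Worked example

```python
from patenttrends import (
    SimSeriesConfig, simulate_count_series,
    sample_changepoint_posterior, SamplerConfig,
    yearly_percent_changes, mean_percent_change, peak_month,
)

cfg = SimSeriesConfig(
    n_months=120, mu_early=2.0, mu_late=10.0,
    changepoint_month=60, seed=42, taxon="pangolin", start_month="1995-01",
)
series = simulate_count_series(cfg)                      # planted shift at 2000-01
post = sample_changepoint_posterior(series, config=SamplerConfig(seed=7))
print(f"MAP changepoint month: {post.map_month}")
print(f"P(tau = MAP):          {post.concentration:.3f}")
print(f"converged (R-hat < 1.01): {post.converged}")
summary = yearly_percent_changes(series, 1996, 2004)
print(f"mean year-on-year change: {mean_percent_change(summary):+.1f}%")
print(f"peak month: {peak_month(series)}")
```

prints

```
MAP changepoint month: 2000-01
P(tau = MAP):          0.328
converged (R-hat < 1.01): True
mean year-on-year change: +38.6%
peak month: ('2000-03', 50)
```

The posterior mode lands exactly on the planted month (index 60 from
1995-01): a five-fold rate jump at φ = 1 is detectable but the posterior
spreads over neighbouring months, which is why the full `tau_probs`
distribution, not just the mode, is the primary output. The mean
year-on-year change (+38.6 %) reflects the jump passing through the
1996–2004 comparison window, and the peak month is the noisiest high-rate
month after the shift.

The same analysis runs from the shell on a YAML config:

```bash
patenttrends run --config config.yaml --seed 1
patenttrends changepoint --series out/series_pangolin.csv --seed 1 --out out/
patenttrends trends --series out/series_pangolin.csv --start-year 1996 --end-year 2004
```

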