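# Methods

This note documents the statistical models, algorithms and design choices in
`patenttrends`, in the package's own terms: what is computed, under which
assumptions, with which defaults, and what the synthetic-data experiments do
and do not demonstrate.

## 1. Data model

A patent record carries an opaque unique id, title, abstract, priority date
(the date of first filing — the event timestamp used throughout),
jurisdiction, applicants and a taxon tag. The default study window is
1970-01 to 2020-12; records outside it are rejected at ingest with per-line
error reports, never silently dropped. Deduplication collapses records
sharing an id, keeping the earliest priority date (patent families are not
modelled). Monthly aggregation assigns each record to the calendar month of
its priority date; day and timezone are ignored because every downstream
consumer is monthly.

Keyword filtering implements include/NOT-exclude semantics: a record is kept
iff at least one include term matches and no exclude term matches, exclusion
overriding inclusion. Matching is case-insensitive; Latin-script terms bind
to word boundaries with multi-word terms matched as contiguous phrases,
while terms containing non-Latin characters (e.g. CJK strings such as 穿山甲)
match as literal substrings, since word boundaries are undefined there. By
default titles and abstracts are searched; the field set is configurable
because sources differ in which fields their search engines index.

## 2. Changepoint model

Monthly counts are negative binomial in the NB2 parameterization: mean μ,
dispersion φ, variance μ + μ²/φ (Poisson as φ → ∞). A single changepoint
τ ∈ {1, …, n−1} — the index of the first "late" month — switches the
parameters:

    y_t ~ NB2(μ_e, φ_e)  for t < τ,    y_t ~ NB2(μ_l, φ_l)  for t ≥ τ.

Priors: μ_e, μ_l ~ Exponential(mean 10); φ_e, φ_l ~ Exponential(mean 1);
τ ~ DiscreteUniform{1, …, n−1}. The exponential family was chosen for its
positive support and weak information at these scales; the prior means are
configuration knobs (`ChangepointPriors`). Every interior month boundary is
a candidate.

### Inference

τ is never sampled directly. The marginal likelihood of the four continuous
parameters is computed by log-sum-exp over all candidate τ (prefix/suffix
sums of per-month log-pmfs make this O(n) per evaluation), and the reported
per-month changepoint probability is the Rao-Blackwellized posterior mean of
P(τ | θ, y) over post-warmup draws. This is smoother and lower-variance than
histogramming sampled τ values.

The MCMC kernel is componentwise slice sampling with stepping-out (Neal
2003) on the logs of (μ_e, μ_l, φ_e, φ_l). Slice sampling was preferred over
an acceptance-targeted random-walk kernel because it is rejection-free and
self-tuning: step widths are set once from the warmup sample spread, and a
target-acceptance knob that would throttle a Metropolis proposal has no
analogue, so `SamplerConfig.target_accept` is accepted for interface
compatibility but is inert for this kernel. Defaults: 2000 iterations, 4
chains, first half discarded as warmup, overdispersed starts drawn from the
priors. Convergence is assessed with split R-hat and effective sample size
per parameter (Section 4); a fit with any R-hat ≥ 1.01 is flagged
non-converged, never hidden. NaN log-densities abort with a diagnostic.

### Exact oracle

`exact_changepoint_posterior` integrates the four parameters on a log-spaced
quadrature grid (64 μ-nodes, 48 φ-nodes by default; μ-range data-driven,
φ-range 0.02–200) with exponential-prior weights and the log-spacing
Jacobian. Given τ, the early and late blocks factorize, so the 4-d integral
reduces to two 2-d sums reusing one pmf matrix, and the oracle is cheap and
exact up to grid resolution. It refuses series longer than 120 months — it
exists to validate the sampler at modest lengths (total-variation agreement
≲ 0.02 in the test suite), to verify exact time-reversal symmetry of the
posterior, and to serve as ground truth in recovery experiments. The
posterior is reversal-symmetric because the τ prior is uniform and the early
and late priors are identical.

### Segmentation

Multiple shifts are found by recursive binary segmentation: fit, split at
the MAP changepoint, re-fit each half. A segment is split only while the
segment budget allows, both halves would have at least `min_segment_length`
(default 24) months, and the posterior is concentrated — max τ probability
at least twice the uniform level 2/(n−1). The stopping rule is a pragmatic
default, not an inferential claim; joint multiple-changepoint models are out
of scope.

## 3. Why the 120-month recovery experiment sits near its ceiling

The planted-recovery study conditions (n = 120, μ 2 → 10 at τ = 60,
φ_e = φ_l = 1) are intentionally noisy: at φ = 1 the late regime has
variance μ + μ² = 110, so a run of low-count months just after the true
changepoint is common. Calibration with the exact oracle over 200 simulated
series shows the Bayes-optimal posterior mode lands within ±3 months of the
truth in ~91% of realizations, and the joint event "mode within ±3 and ≥90%
of mass within ±12" in ~88%. The sampler reproduces the exact posterior
(identical modes on every tested seed), so recovery failures under these
conditions are a property of the data process, not of the inference; no
estimator can do better than the exact posterior it matches.

## 4. Convergence diagnostics

Split R-hat halves each chain, then compares within- to between-half-chain
variance: R̂ = sqrt(((n−1)/n · W + B/n) / W). Effective sample size uses the
multi-chain autocovariance (FFT) with Geyer's initial monotone positive-pair
truncation. Zero-variance chains return NaN as an explicit "undefined"
sentinel rather than erroring. Per-parameter trace arrays are exported for
visual inspection. Both statistics are cross-checked against an independent
implementation (arviz) in the test suite.

## 5. Topic model

LDA with symmetric Dirichlet priors: document-topic concentration
α = 50/K (Griffiths–Steyvers heuristic, rescaled when K changes during model
selection), topic-word concentration η = 0.01. Inference is collapsed Gibbs
over token-topic assignments; the sweep kernel is numba-JIT-compiled with an
identical pure-Python fallback, and per-sweep uniforms are pre-drawn from a
seeded generator so results are bit-reproducible and independent of the JIT.
Defaults: 1000 sweeps, 500 burn-in. Point estimates come from the final
smoothed counts. The total assigned-token count is recorded after every
sweep as a conservation audit, and the collapsed joint log p(w, z) is traced
for monitoring.

Preprocessing tokenizes abstracts on unicode word boundaries, lowercases,
removes a small English function-word stoplist and terms rarer than
`min_term_count` (default 2) corpus-wide; emptied documents are dropped with
a report.

**Coherence** is UMass: for a topic's top-N terms ranked by probability,
Σ_{m>l} log((codf(v_m, v_l) + 1) / df(v_l)), corpus-internal document
frequencies, +1 smoothing, denominators floored at 1 so unseen terms never
divide by zero. **Exclusivity** is the mean, over a topic's top terms, of
P(w|k) / Σ_k' P(w|k') — in (0, 1], equal to 1 iff the top terms carry no
mass elsewhere. **Topic-number selection** fits each K in a grid, min-max
normalizes mean coherence and mean exclusivity across the grid, and picks
the K maximizing their unweighted mean; the full score table is returned for
human review because the balance is a heuristic, not a likelihood criterion.

"Generic" terms — excluded from top-term lists and codebooks — are the
stoplist plus terms appearing in more than half the documents.

## 6. Thematic coding

A codebook maps thematic labels (medicine, food, cosmetics, synthetics,
farming, processing, detection, agriculture, electronics, leather, snuff by
default — fully configurable) to keyword lists. It is seeded from the first
five non-generic top terms of each LDA topic via a topic→label map, plus
configured standard terms (e.g. "pain" under medicine); duplicates keep the
LDA provenance, and every keyword carries a provenance tag
(`lda_top_term`, `standard_term`, `expansion_iteration_k`).

Coding is multi-label with the same matching rules as keyword filtering, and
every assignment is backed by a stored (record, keyword, label) triple for
audit. Iteration: while coverage < 1, an expansion policy proposes keywords
for uncovered records. The automated default appends each uncovered record's
most frequent non-generic term to the label of its highest-probability LDA
topic; the policy is an injectable callable precisely so that a human review
step can replace it. Coverage is monotone because keywords are only added; a
policy that proposes nothing while records remain uncovered terminates with
an explicit non-convergence flag. The original workflow this automates used
manual review; the deterministic policy exists for testability and makes no
claim to match human judgement.

Cumulative label proportions (the diversification view): for each month, the
share of each label among all label assignments to records dated at or
before that month. The denominator is total assignments, not unique records
— a two-label patent counts twice — so rows sum to 1 once any label exists.

## 7. Trend statistics

Year-on-year change compares January–December totals:
100 · (T_y − T_{y−1}) / T_{y−1}. Years whose previous year had zero filings
are skipped and reported; the mean percentage change averages defined
changes only. The comparison start year is a required explicit argument —
studies differ on when to start (e.g. the first year all taxa have filings)
and a silent default would hide that choice. Period medians use the standard
even-length mean-of-central-pair rule; peaks break ties toward the earliest
month; the display smoother is a centered moving average with
truncated edges, default 13 months (the closest odd span to a year, so the
window stays centered).

## 8. Synthetic data: what it emulates and what it does not

The generator plants ground truth for every downstream stage: NB2 count
series with an abrupt parameter shift; abstracts as bags of Latin-script
pseudo-word tokens drawn from a planted topic mixture (topic-word rows
either Dirichlet-sampled or pinned explicitly, e.g. disjoint supports for
recovery experiments); one taxon include keyword per record; a configurable
fraction of records carrying a decoy exclusion term (emulating confounders
like the fruit-fly gene named pangolin); priority dates uniform within each
month. Everything is deterministic in the seed.

It deliberately does **not** emulate: real legal prose or grammar,
multilingual text (decoys and keywords are literal tokens, keeping the tests
tokenization-neutral), patent families or citation structure, jurisdictional
filing dynamics, or Zipfian corpus-wide term frequencies (except where a
geometric within-topic profile is planted for selection experiments — peaked
term distributions are what make near-duplicate split topics detectable by
exclusivity, mirroring real text). Passing recovery tests therefore
demonstrate the estimators' correctness under the planted model, not
performance on scraped patent corpora, which are noisier in ways the
generator does not represent.

Default experiment sizes (120-month series; corpora of a few hundred
documents of ~40–50 tokens; 10–20 replicates) were chosen as the smallest
scales at which the planted effects are statistically identifiable, keeping
the full test suite and the reproduction script in the minutes range on a
single CPU.

## 9. Numerical choices and degenerate inputs

- NB2 log-pmf via log-gamma composition; finite for all valid inputs;
  parameters must be strictly positive.
- Log-parameters are clamped to |log x| ≤ 30 during sampling to avoid
  overflow; the marginal likelihood uses stabilized log-sum-exp throughout.
- τ posteriors are renormalized after exponentiation; the package-wide
  tolerance for "sums to 1" is 1e−8.
- Slice sampling shrinkage that collapses below width 1e−12 keeps the
  current point (a theoretical corner case; never observed in tests).
- Stage seeds in the pipeline derive from the global seed via CRC32-keyed
  `SeedSequence`, so runs are reproducible across processes and platforms;
  the run report contains no timestamps, making reruns byte-identical.
- Empty corpora, all-stopword documents, zero-variance chains, empty
  aggregation windows and out-of-range τ all raise explicit errors or return
  documented sentinels rather than propagating NaNs.

## 10. Known limitations

- Single-changepoint model per (sub)series; gradual ramps are approximated
  by one or more abrupt shifts.
- The quadrature oracle's grid is fixed per call; pathological posteriors
  far outside the data-driven μ-range would need a custom grid.
- The collapsed-Gibbs point estimate uses final counts, not an average over
  draws; label switching across runs is handled in evaluations by
  best-permutation matching.
- Coherence/exclusivity selection is a heuristic balance; the score table
  should be reviewed rather than trusted blindly.
- The automated codebook-expansion policy guarantees coverage, not semantic
  fidelity; real deployments should use the review hook.
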