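# Methods

`stratamiss` studies what happens to regression inference when a survey's
sampling strata are built from an error-prone categorical variable. The
setting is a single-center patient cohort: the exposure of interest,
race/ethnicity (five categories: White, Black, Asian, Other, Hispanic), is
also the variable the sampling design stratifies on — but the design only
sees the EHR-recorded value `X*`, which disagrees with the self-reported
(taken as true) value `X` for a nontrivial fraction of patients. The
outcome `Y` is binary trust in the healthcare system; a second binary
covariate, low income, is *not* used for sampling.

## Generative model

Each replicate draws a finite population of `N = 100,000` units:

1. `X ~ Categorical(0.82, 0.10, 0.01, 0.05, 0.02)` over (White, Black,
   Asian, Other, Hispanic) — survey-weighted estimates of the true
   population composition of the motivating cohort;
2. `low_income | X ~ Bernoulli(expit(-2.00 + 1.25·Black + 0.25·Asian +
   1.75·Other + 0.50·Hispanic))`;
3. `Y | X, low_income ~ Bernoulli(expit(-0.75 - 0.25·Black - 0.50·Asian +
   1.25·Other - 1.50·Hispanic + 1.00·low_income))`.

The coefficient vector `(-0.75, -0.25, -0.50, 1.25, -1.50, 1.00)` is the
ground truth every estimator is judged against. White is the reference
category throughout; dummies drop it.

## Misclassification mechanisms

`X*` is drawn per unit from a row-stochastic generator matrix
`Pr(X* = j | X = i[, Y])`. Two families are provided.

**Empirical.** The package embeds, verbatim, the 604-respondent
cross-tabulation of EHR-recorded (rows) against self-reported (columns)
race/ethnicity from the Vanderbilt University Medical Center arm of the
CERC biobank survey — overall, and split by the trust outcome. The split
tables differ (e.g. the recorded-Hispanic diagonal is 60.7% among
distrusting vs 49.2% among trusting respondents), which is what makes the
outcome-stratified mechanism *differential*: conditioning on `X*` then
opens a collider path between `X` and `Y`.

The table's row percentages are `Pr(true | recorded)` — the *wrong
direction* for generation. Two conversions are exposed as
`matrix_interpretation`:

* `bayes_inverted` (default): Bayes inversion with a uniform prior over
  the recorded categories, i.e. each *column* of the row-percentage
  matrix, renormalized, becomes the generator row for that true category.
  This is the package's reference mechanism: under it the simulation
  reproduces the motivating study's published operating characteristics
  essentially cell for cell (see `scripts/acceptance.py`).
* `direct`: reuse the row percentages as generator rows (re-indexing rows
  as true categories). Kept because it is the naive reading; it yields a
  materially different design — e.g. roughly 280 rather than ~60 true
  Hispanics per stratified sample — and correspondingly smaller SEs.

General re-conditioning is available via `invert_direction`, which solves
for the conditioning-variable marginal consistent with a supplied target
marginal, builds the joint table, and renormalizes.

**Degree-parameterized.** `degree_matrix(d)` puts `1 - d` on the diagonal
and spreads mass `d` off-diagonal, uniformly (`d/(H-1)` each) or
proportionally to the empirical off-diagonal row profile. `d` sweeps from
0 (no misclassification) to 0.5 (half the population mislabeled) in the
relative-uncertainty analysis. How off-diagonal mass is distributed at a
given `d` is not uniquely determined by the motivating study; both
patterns are provided and the uniform one is the sweep default.

## Designs and weights

* **SRS**: `n = 2,500` uniform without replacement; weights `N/n`.
* **DSS** (disproportionate stratified sampling): 500 units without
  replacement from each of the five `X*` strata; a unit from stratum `h`
  carries weight `w_i = N*_h / n*_h`, the inverse of its realized
  selection probability, so Horvitz–Thompson stratum totals are exact. A
  quota exceeding a stratum takes the whole stratum (weight 1) with a
  warning; an empty stratum contributes nothing and is recorded.
* `truncate_weights` caps weights at a percentile of their distribution
  (linear interpolation between order statistics, the numpy default) —
  the operation used on real survey weights to trade a little bias for
  variance; it is not part of the simulation pipeline.

No finite-population correction is attached: variance estimation uses the
with-replacement approximation, which is slightly conservative at these
sampling fractions.

## The three analysis strategies

All three model `logit Pr(Y=1) = β0 + Σ_h β_h X_h + β_L·low_income` on the
*true* category dummies:

* **design-agnostic** — ordinary ML, ignoring the design;
* **model-based** — ordinary ML adding the recorded-category dummies
  `X*_h` as covariates;
* **design-based** — weighted pseudo-ML maximizing
  `Σ_i w_i [y_i log p_i + (1-y_i) log(1-p_i)]`, with Taylor-linearization
  ("sandwich") variance `A⁻¹ B A⁻¹`, where `A` is the negative Hessian of
  the weighted log-likelihood and `B = Σ_i u_i u_iᵀ` with
  `u_i = w_i (y_i - p_i) x_i`.

The sandwich default treats weighted units as independent
(`variance="unstratified"`); `variance="stratified"` centers scores within
sampling strata with the `n_h/(n_h-1)` factor. The unstratified form is
the default because it is the common survey-software default when no
stratum information is attached to the design object, and it reproduces
the published design-based coverage (e.g. ~92% for the Asian coefficient
under differential misclassification); both forms are available.

## Numerical choices

* **Fitting**: iteratively reweighted least squares from `β = 0`, with
  step-halving so the objective never decreases; convergence when the
  relative deviance change is below `1e-8`, at most 25 iterations — the
  same stopping rule R's `glm` uses, deliberately, so separated fits
  behave identically (below).
* **Separation**: a covariate cell with no successes drives its
  coefficient to a plateau near −15 on the log-odds scale before the
  deviance stabilizes; R's `glm` reports such fits as converged and they
  are *retained* here too. Only fits whose coefficients pass |30| — i.e.
  genuinely diverging ones — are flagged non-converged and excluded from
  Monte-Carlo summaries, per cell, with counts reported. This retention
  matters: the SRS empirical SEs of the rarest-group coefficients are
  dominated by exactly these replicates.
* **Rank**: all-zero dummy columns (category absent from the sample) and
  aliased columns (e.g. `X* ≡ X` at misclassification degree 0) are
  dropped with a logged note, mirroring R's aliasing behavior;
  `fit_logistic` itself raises on a rank-deficient design, naming the
  offending columns.
* **Intervals**: Wald, normal quantiles, 95% by default. Coverage is the
  fraction of (converged) replicates whose interval contains the
  generating coefficient. Recorded-category dummies have no generating
  value and report NaN coverage.
* **Full-cohort fits** collapse the population into covariate-pattern
  cells with frequency weights before IRLS — algebraically identical
  coefficients, information and log-likelihood, at ~1/1000 the cost.

## Randomness

One parent seed per scenario; replicate `r` uses
`SeedSequence((seed, r))`, so any replicate is reproducible in isolation
and results do not depend on execution order. Identical configuration +
seed gives byte-identical output CSVs.

## Monte-Carlo summaries and replication counts

Per (design, method, parameter): mean estimate, empirical SE (SD of
estimates across replicates), 95% coverage, and convergence counts.
Relative uncertainty is `SE_DSS(method) / SE_SRS` per parameter, reported
with its log2.

The bundled main configuration uses the study's 10,000 replicates, as
does `scripts/acceptance.py`. The test suite uses a 2,000-replicate
profile. One caveat documented here because it is easy to trip over: the
empirical SEs of the Asian and Hispanic coefficients under SRS (and, less
so, under DSS) are dominated by the Poisson-distributed count of
separated replicates — each adds roughly `(15 − β̄)²/R` to the sampled
variance — so at `R = 2,000` those SD statistics themselves fluctuate by
tens of percent across seeds, far beyond the normal-theory
`SE/√(2(R−1))` error formula. Mean and coverage summaries are stable at
`R = 2,000`; rare-group SD summaries are not, and should be read at the
full replication.

## What the generator does and does not emulate

The synthetic populations reproduce the study conditions exactly: the
categorical exposure distribution, the two logistic data-generating
models, and misclassification rates taken from a real respondent sample.
They do not emulate non-response (the motivating survey had a 16%
response rate), continuous covariates, multi-stage or 288-stratum
designs, or misclassification of the outcome or of income. Passing tests
therefore demonstrate the estimators' operating characteristics under the
stated design, not robustness to those further complications.

## Known limitations

* The design-based variance offers no small-stratum safeguards beyond
  refusing single-unit strata in stratified mode.
* No Firth or other penalized fallback for separation — plain ML is the
  object of study, and separated fits are part of the reported
  distributions.
* The degree sweep's off-diagonal allocation is a modeling choice (two
  options shipped), not an estimate.
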