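# Methods

## Model and likelihood

The mean curve is the four-parameter exponential for continuous endpoints,
`mean(x) = a·[c − (c−1)·exp(−(x/b)^d)]`, the unique form consistent with
the parameter meanings used throughout the package: `mean(0) = a`, upper
asymptote `a·c`, potency `b` in dose units, log-steepness `d`. The error
model is lognormal: `ln y ~ N(ln mean(x), var)` with a single `var` shared
across dose groups and — in combined fits — across datasets. The
likelihood convention is the density of the log-response (no Jacobian
term); the same convention is used in fitting, profiling and the public
`log_likelihood`.

A combined fit over K datasets estimates `{a_i, b_i}` per dataset plus
shared `(c, d)`. The likelihood is maximized by exploiting separability:

1. `var` is concentrated analytically (its MLE given the mean parameters
   is the mean squared log-residual);
2. for fixed `(c, d)`, each `ln a_i` has a closed-form optimum (the mean
   log-residual against the unit-background curve) and each `b_i` is a
   one-dimensional search, performed on a 41-point log-spaced grid
   spanning ±ln 50 around the dataset's top dose with parabolic
   refinement;
3. the remaining two-dimensional problem in `(ln(c−1), ln d)` is solved by
   Nelder–Mead with seeded multi-starts (default 10; the heavy simulation
   paths use 3), followed by a joint L-BFGS-B polish over all
   `(ln(c−1), ln d, ln b_i)` with `a_i` and `var` still concentrated.

Noise-free data are recovered to ~1e-6 relative error; a 47-dataset,
~1000-observation combined fit takes well under a second on one core.

`d` is restricted to [0.25, 8] (configurable) as a steepness guardrail.
Datasets with fewer than three distinct dose levels cannot identify `d`;
`fit_single` then fixes `d = 1` and flags the result. By default `d` is
shared across datasets like `c`; `FitOptions(share_d=False)` switches to
per-dataset `d` via the same separable machinery (no `c` profile is
offered in that mode).

## Reported variance: degrees-of-freedom correction

The concentrated MLE `SSE/N` is biased low by roughly `p/N`, where
`p = 2K + 2` counts the mean-curve parameters — a Neyman–Scott situation
that is material here (`p ≈ 96`, `N ≈ 1000` gives ~9% downward bias,
comparable to the width of the 90% interval). `FitResult.var` therefore
reports the degrees-of-freedom corrected residual variance `SSE/(N−p)`,
the standard residual-variance estimator in (non)linear regression, and
the profile deviance for `var` is scaled by `ν = N−p` accordingly:
`D(v) = ν·[ln(v/v̂) + v̂/v − 1]`, with the 90% interval at the χ²₁ 0.90
quantile (2.7055). In simulation this estimator is near-unbiased and its
interval covers the truth at close to nominal rate, which the raw MLE
cannot do at this parameter-to-observation ratio. The raw MLE remains
available as `FitResult.var_mle` and satisfies the exact mean-squared
log-residual identity.

One visible consequence: fitting a dataset together with an exact copy of
itself reproduces `c`, `d` and `var_mle` exactly, while the reported `var`
shifts slightly because the copy changes `N − p`.

## Profile intervals for c and the BMD

The `c` profile re-optimizes `(d, b_i)` at fixed `c` (warm-started
L-BFGS-B) and brackets the deviance crossing by bisection on the `ln(c−1)`
scale. The `b` box during profiling extends far above the dose range
because large `c` trades off against large `b` along a near-flat ridge
(the power-law limit of the model); truncating that ridge would fabricate
finite upper bounds. When no crossing occurs below a cap (default
`c ≤ 10⁶`) the upper bound is reported as `+inf` — the expected outcome
for data without a high-dose plateau. The BMD at benchmark response `r`
has the closed form `b·[−ln((c−1−r)/(c−1))]^(1/d)` (independent of `a`);
BMDL/BMDU re-parameterize `b` in terms of the BMD and profile it the same
way.

## BMR computations

* Effect-size route: `BMR = exp(f·k·√var) − 1` with `f = 1/8` and `k = 7`
  (90% CI 5.9–8.9, exposed via `bmr_k_sensitivity`); interval endpoints
  propagate through the monotone map. The `c`-based variant
  `BMR = c^f − 1` agrees exactly whenever `ln c = k·√var`.
* One-SD suite: all three variants are dimensionless dispersion/location
  ratios, so they are scale-invariant. Study-specific: per-study SD/mean
  aggregated by the median (configurable to mean; the median is robust to
  occasional noisy small studies). Historical SD: the pooled control
  distribution is right-truncated by removing the `ceil(0.05·n)` largest
  values — a deterministic reading of "excluding the uppermost 5%" — and
  summarized as trimmed SD / trimmed mean. MAD: `median(|x − median|)`,
  scaled by 1.4826 by default so it estimates the SD under normality,
  divided by the median. On lognormal controls with log-variance `v` the
  study-specific ratio converges to `√(e^v − 1)` as group sizes grow.

## Covariate screen

Datasets are grouped by factor level; one combined fit per level yields
`var` with its 90% profile interval, and the factor is flagged
non-influential when every pair of level intervals overlaps. This is a
deliberate formalization of the visual judgment such analyses usually
rest on; a likelihood-ratio diagnostic (shared vs level-specific `var`)
is available but does not drive the flag. Levels with a single dataset
are marked low-information. Box-plot exports use single-dataset fits so
each point is one dataset's own `var`.

## Synthetic data generator

`generate_database` draws responses exactly from the model the analysis
assumes: lognormal noise with shared `var_true` around exponential curves
with per-dataset `(a_i, b_i)` and shared `(c, d)`. Defaults describe the
flagship Duplex Sequencing collection: 47 datasets; `var_true = 0.078`,
`shared_c = 17.2`, `shared_d = 1`; 3–5 treated dose levels per dataset in
geometric spacing (factor 2.5) under a top dose drawn log-uniformly from
10–200 mg/kg BW/day; 3–6 animals per group; background `a` log-uniform on
0.5–5 mutations per 10⁸ bp (an order-of-magnitude choice — typical
technology-specific background means are not tabulated in the primary
sources); potency `b` log-uniform on 0.2–1.5 × top dose so curvature is
visible within the dose range. The covariate design reproduces the
published per-factor dataset counts (39 mouse / 8 rat, 25 MutaMouse, 42
gavage, and so on), with species derived from strain so assignments stay
consistent. `control_n_total = 216` reproduces the pooled
historical-control count. A master seed spawns per-dataset substreams, so
growing a database never perturbs earlier datasets.

What the generator does **not** emulate: sequencing-level error processes
(duplex consensus, clonal correction), non-lognormal tails, dose-dependent
variance, and the empirical between-study distribution of background
mutation frequencies. The last point matters when interpreting the
pooled historical-control BMRs: with backgrounds spread over a 10-fold
range, the pooled control distribution mixes between-study with
within-group variability, so the synthetic historical-SD/MAD BMRs (~50–65%)
sit well above the study-specific value (~28%), whereas the real DupSeq
control pool is evidently much tighter (published values 22.6–28.8%).
Passing tests therefore demonstrate correctness of the estimators and the
pipeline, not that real control pools behave like the synthetic mixture.

## Numerical and reporting choices

* Deviance threshold χ²₁(0.90) = 2.7055 for all 90% profile intervals;
  `level=0` degenerates to the point estimate.
* Optimizer determinism: all stochastic elements (multi-start jitter)
  derive from the user-supplied seed; repeated fits are bit-identical.
* Zero responses are rejected at ingestion by default (the log-likelihood
  is undefined at 0); `zero_policy="half_min"` substitutes half the
  smallest positive response of the same dataset.
* Report rendering rounds percentages to one decimal and variances to
  three decimals; all internal computation is full precision. Because the
  published variance estimates are themselves rounded to three decimals,
  BMRs recomputed from them can differ from published percentages in the
  last decimal (0.031 → 16.65%, 0.057 → 23.23%).
* Simulation problem sizes in the test suite: 100 replicates of the
  47-dataset design for coverage/bias of `var` (3 multi-starts per
  replicate), 30 replicates per condition for the data-paucity
  comparison. These sizes give Monte-Carlo error comfortably below the
  asserted margins.

## Known limitations

* The incidental-parameter correction uses a fixed dof count `p`; it does
  not account for parameters at bounds (e.g. `d` hitting a guardrail).
* The covariate screen tests factors one at a time; confounded designs
  (e.g. strain nested in species) are screened marginally, as in the
  original analysis style.
* No nested/litter random effects; animals are treated as independent.
* Route-specific dose-unit conversions (inhalation, diet, drinking water)
  are out of scope; doses must arrive as (cumulative or daily)
  mg/kg BW/day.
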