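# Methods

## The model

`nestvar` fits Gaussian location–scale (double-hierarchical) models to log
inter-visit intervals (IVIs, minutes). Each observation `i` contributes

    log IVI_i ~ Normal(mu_i, sigma_i)
    mu_i        = b0 + b_age age_i + b_brood brood_i
                  + site_{s(i)} + pair_{p(i)} + u0_{y(i)} + u1_{y(i)} age_i
                  [+ u2_{y(i)} brood_i]
    log sigma_i = g0 + g_age age_i + g_brood brood_i + v_{group(i)}

with natural logs throughout. Nestling age is left-zeroed (day 1 coded 0)
and divided by its SD, so `b0`/`g0` describe day-1 provisioning to an
average brood and the slopes are per covariate SD; brood size is centered
and SD-scaled. The model assumes IVIs are conditionally independent given
the linear predictors — no within-day autocorrelation — and that the log
transform makes residuals Gaussian.

A nine-model ladder grows the random-effect structure: `m1a` none (but
always a year random intercept in the sigma part), `m1b` + site, `m1c`
pair instead, `m1d` site + pair, `m1e` + year intercept, `m1f` + year age
slope, `m1g`/`m1h` as `m1e`/`m1f` but with the year-level effects
(u0[, u1], v) jointly multivariate normal with a full correlation matrix,
`m1i` additionally a year brood slope. The *across-pairs* variant keeps
site and year intercepts in the mean part but moves the age slope and the
sigma intercept to the pair level (pair-level triple jointly MVN); a flag
optionally retains a year sigma intercept alongside.

The correlation entries are the scientific payload of the correlated
models: `rho(intercept, log sigma) < 0` means groups (years or pairs) that
provision faster at baseline are also the more variable ones.

## Priors

Weakly informative, on the standardized-covariate scale; all configurable
via `PriorConfig`:

| parameter | prior | rationale |
|---|---|---|
| mean intercept `b0` | Normal(mean(log IVI), 5) | centers the chain; 5 log-units is vague |
| mean slopes | Normal(0, 2.5) | standardized covariates |
| sigma-part coefficients | Normal(0, 1) | log-SD scale; e^±2 covers any plausible spread |
| group SDs | half-Normal(0, 1) | gentle shrinkage toward 0 for weakly informed SDs |
| correlation matrices | LKJ(2) | mild pull toward independence, full support |

The LKJ prior is realized through canonical partial correlations (CPCs):
independent shifted-Beta priors on the CPCs of a C-vine are exactly
equivalent to LKJ(eta) on the correlation matrix, and the tanh-CPC
parameterization gives an unconstrained vector with cheap closed-form
gradients. A unit test verifies the induced marginals (Beta(2.5, 2.5) on
(−1, 1) for d = 3, eta = 2).

## Sampling and diagnostics

The posterior is explored with an in-house No-U-Turn sampler: multinomial
sampling along doubling leapfrog trajectories, generalized u-turn
criterion, dual-averaging step-size adaptation (target acceptance 0.9)
and Stan-style expanding windows for a diagonal mass matrix. All random
effects are non-centered (effects = SD x Cholesky x z), which is what
keeps the correlated mean/sigma blocks sampleable. Gradients of the log
posterior are analytic (grouped sums via bincount), including the
backward pass through the CPC-to-Cholesky recursion; they are checked
against finite differences for every ladder spec in the test suite.

Defaults: 4 chains x (1,000 warmup + 1,000 draws), max tree depth 10.
A fit raises a `ConvergenceError` when divergences exceed 1% of draws, or
(with `check=True`) when any reported parameter has R-hat > 1.01 or
ESS < 400 (computed via arviz). Reduced-draw fits (model-ladder scans,
test-suite runs) pass `check=False` and assert the diagnostics they need
explicitly. Energy errors above 1000 count as divergences; the divergent
subtree is discarded.

Degenerate inputs: a one-observation frame yields a wide posterior or a
convergence error, never a crash; non-finite posterior at initialization
raises immediately; `log sigma` under/overflow is treated as a divergence
through the Hamiltonian check.

## Model comparison (PSIS-LOO)

`psis_loo` turns the pointwise log-likelihood matrix (draws x
observations) into leave-one-out expected log predictive densities: raw
importance ratios `1/p(y_i | theta_s)`; the largest `min(0.2 S, 3 sqrt(S))`
weights per observation are replaced by expected order statistics of a
generalized Pareto fitted to the exceedances (Zhang–Stephens
profile-posterior estimator, prior-regularized shape), truncated at the
raw maximum. Tail shapes k > 0.7 are flagged, not corrected (no moment
matching, no refits). Degenerate all-equal weights report k = −inf and
reproduce the common value exactly. `compare` ranks models by elpd with
*paired* pointwise differences against the best model (se_diff from the
paired vector), dense ranks with ties broken by parameter count then
name, and flags models within 2 elpd units of the best as indiscernible.
The implementation is cross-checked against an exact closed-form
leave-one-out calculation on a conjugate Gaussian toy and against
`arviz.loo` in the tests; those checks are oracles, not dependencies.

## Posterior summaries

Every reported quantity is an `EffectSummary`: posterior **mode**
(Gaussian KDE, Silverman bandwidth, argmax on a 512-point grid spanning
the draw range — deterministic given draws), equal-tailed 95% credible
interval, and a support category: *strong* when the CI excludes zero,
*moderate* when at most 15% of posterior mass sits on the minority side
of zero (at least five-fold directional support), *none* otherwise. A KDE
mode may legitimately fall outside an equal-tailed CI for skewed
posteriors; this is exposed as a flag rather than treated as an error.
Modes need at least 400 draws.

Year summaries: intercept `b0 + u0_y` (log minutes; `back_transform`
maps to minutes/hours), slope `b_age + u1_y`, and `sigma_exp =
exp(g0 + v_y)` — the year's residual SD of log IVI at baseline
covariates, reported on the exponentiated scale.

Variance partition: intercept-like random terms contribute `sd^2`, random
slopes `sd^2 * mean(x^2)` over the observed standardized covariate, and
the residual is `E[sigma_i^2]` averaged over the observed covariate
distribution (sigma-part random effects therefore live inside the
residual share). Shares are computed per draw and sum to one by
construction.

## The synthetic-data generator

The generator emulates the study design the model assumes: 7 years, 51
sites, site-year occupancy tuned so ~99 pairs are active, brood sizes 1–4
(probabilities 0.10/0.25/0.40/0.25), nestling ages 1–12, log-normal IVIs
with the location-scale structure above, a camera-failure rate under 0.5%
and rare biologically impossible gaps (> 4,000 min). Defaults for the
generating parameters are the published across-years point estimates
(`b = (5.40, −0.18, −0.12)`, `g = (log 0.72, 0.08, −0.01)`, site SD 0.14,
pair SD 0.19); year-effect SDs (0.10, 0.12, 0.12) match the spread of the
published year-specific intercepts, slopes and sigmas. Year effects can
be drawn from a user-supplied correlation matrix or fixed verbatim (the
recovery tests for year-specific quantities fix them); the truth record
states which, and also reports the design-wide covariate SDs used for
standardization inside the generator.

**Stream construction.** Each nest runs one continuous renewal stream
from hatch through day 12: every interval is drawn from the log-normal of
the day on which it *starts* (matching the preprocessing rule that an
interval's nestling age is its start-day age, and that midnight-spanning
intervals are kept). Recorded intervals per day are capped by a
Poisson(`mean_visits_per_day`) draw — a value-independent thinning that
sizes the dataset (~5,000 records at the default 4.5) without biasing the
interval distribution. Only the stream-terminating interval of each nest
is discarded. An earlier per-day scheme that discarded each day's
boundary-crossing interval was rejected after measurement: the crossing
interval is size-biased upward, so discarding one per day biased the
recorded sample low (intercept −0.09, largest year sigma_exp 0.74 instead
of 0.85 in simulate-and-refit). Interval lengths are rounded to whole
minutes (events have minute resolution); the rounding is negligible at
IVI scales of hours.

Event logs realize the same streams as timestamped rows (hatch dates
uniform over July 1–14, which carry no effect), including day-0 visits
that preprocessing must drop. Wherever the Poisson cap (or an injected
outlier gap) leaves a span unrecorded, a single camera-off `fail` row is
written inside the gap, so the preprocessing rules drop exactly the
unrecorded intervals: at zero failure/outlier rates,
`compute_ivis(generate_event_log(...))` equals `generate_ivi_table(...)`
record for record, and the tests assert it.

**What the generator does not emulate** — and hence what passing recovery
tests do and do not show: no diurnal activity rhythm, no within-day
autocorrelation or behavioural bout structure, no heavy-tailed residuals
beyond the log-normal, no missing-by-weather camera outages, no
prey-type/biomass structure, no parental-sex attribution. Recovery here
demonstrates that the estimation machinery is unbiased and calibrated
under the model's own assumptions, not that field data satisfy them.

## Preprocessing rules

IVI = minutes between start times of consecutive visits within a nest;
intervals adjacent to a `fail` row are dropped; age = start-visit day
relative to hatch of the first-hatched nestling; day-0 and age > 12
intervals are dropped; in years without a time-lapse backstop, intervals
above 4,000 min are removed (the outlier rule; removal count returned).
Exclusion accounting is conserved and asserted: adjacent-row pairs =
kept + fail-dropped + day0-dropped + age-dropped. Covariate scaling uses
sample SDs (ddof = 1) computed on the post-exclusion table — the table an
analyst actually has; scaling from a pre-exclusion table is possible by
calling `build_model_frame` before `apply_outlier_rule`. Scaling
constants are stored for exact back-transformation. Food-supplemented
nests are removed via an explicit exclusion list.

## Problem sizes in the tests and the acceptance script

The heavy checks are sized to single-CPU runs: the full-scale
simulate-and-refit uses one ~5,000-record dataset with m1h at 4 chains x
(400–500 warmup + 400–500 draws); the nine-model ladder scan runs at 2
chains x (300 warmup + 500 draws) per model — enough draws that elpd
differences between near-equivalent top models are not Monte-Carlo noise
while staying far below the full-length defaults; the
multi-seed invariants (coverage across replicates, sign recovery) are
exercised at reduced replicate counts and smaller designs in the default
suite. These sizes are the package's choices for routine runs; all
defaults remain the larger values quoted above.

## Known limitations

- The sampler is single-threaded; chains run sequentially.
- Tail smoothing follows the standard PSIS recipe but bad-k observations
  are only flagged.
- Year-level correlations are weakly identified with 7 groups by
  construction; wide CIs there are the expected behaviour, not a defect.
- The published minute-scale slope illustrations (e.g. "a ~20-min
  decrease over days 1–12") depend on the field data's empirical
  covariate SDs and are deliberately out of scope.
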