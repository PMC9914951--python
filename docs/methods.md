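# Methods

## Model and assumptions

The package models the number of drinks `Y` consumed on one drinking
occasion ("occasion" and "drinking day" are used interchangeably
throughout, as the underlying survey items do not distinguish them). The
mechanistic postulate is that an occasion is a sequence of `r` mini
drinking episodes; within an episode each drink is an independent
Bernoulli trial that terminates the episode with probability `p`. Episode
sizes are therefore geometric (failures before the first success), and
their sum is negative binomial in the failures-before-r-th-success
parameterisation:

    P(Y = y | r, p) = Γ(y + r) / (Γ(r) y!) p^r (1 − p)^y .

This parameterisation is fixed by two identities the model relies on:
`P(Y = 0) = p^r` and `E[Y] = r(1 − p)/p`. `r` is continuous (the covariate
link makes it so), so all probabilities are computed in log space with the
log-gamma function; nothing assumes integer `r` except the convolution
oracle used in tests.

Two observational features shape the likelihood:

* **Zero truncation.** Only respondents who drank in the past 30 days are
  modelled, so all probabilities condition on `Y ≥ 1` (divide by
  `1 − p^r`).
* **Right censoring at 20.** Reported last-occasion counts are capped at
  20 drinks; a report of 20 contributes the tail mass
  `P(Y ≥ 20 | Y ≥ 1)`, not a point mass. The usual-drinks covariate `K`
  is capped at 24, which is purely a covariate recode and plays no role in
  the likelihood.

## Covariate links

Individual parameters come from two linear predictors over the same term
universe — eight age-band dummies (reference 20–25), a female indicator,
`u₁ = ln(1/K)`, `u₂ = u₁²`, `v₁ = ln M`, `v₂ = v₁²`:

    r = 1 + exp(a_r + x b_r)        (guarantees r > 1: at least one episode
                                     beyond the geometric baseline)
    p = logistic(a_p + x b_p)       (guarantees 0 < p < 1)

Coefficient sets are stored by term name, never position, so a term
deactivated by model selection cannot misalign the rest. The shipped
reference set (`src/drinkoccasion/data/reference_coefficients.json`)
retains age and gender in the `r` predictor only; its provenance is a
US general-population survey fit (2010–2011 combined years), and it is the
default generating truth for the synthetic-data module.

Under these published coefficients the model-implied mean occasion size
increases with `K` everywhere except one edge cell: at `M = 1` the
`ln(1/K)` quadratic turns over for `K ≥ 20` (mean 9.23 → 9.14 from K=20 to
24). This is a property of the published quadratic, not of the
implementation, and the monotonicity test documents it.

## Estimation

The total log likelihood `lnL = Σ ln l_j` is maximised with L-BFGS-B and a
hand-derived analytic gradient. The censored records' gradient uses the
finite 20-term sum for the cdf, so no special functions beyond log-gamma
and digamma are needed. Numerical choices that matter:

* **Internal standardisation.** The raw design mixes 0/1 dummies with
  `(ln M)²` values up to ~11.6; that conditioning stalls quasi-Newton line
  searches on a substantial fraction of simulated cohorts. The optimiser
  therefore runs on z-scored columns and the solution is mapped back.
* **Convergence criterion.** scipy's L-BFGS-B status flag is unreliable in
  both directions on this problem (premature `ftol` stops with large
  gradients; "abnormal" line-search endings at genuine optima), so
  convergence is declared from the gradient itself:
  `max|∇| ≤ 1e-4 (1 + |lnL|)`. Non-convergence triggers up to three
  seeded jittered restarts and is reported explicitly, never silently.
* **Starting values.** Intercepts from negative-binomial moment matching
  on the raw counts (`p₀ = ȳ/s²` clipped to [0.05, 0.95],
  `r₀ = ȳ p₀/(1−p₀)` clipped ≥ 1.05); slopes start at zero.
* **Saturation guards.** Linear predictors are soft-clipped (η_r at ±50,
  η_p at ±35) so the objective stays finite far from the optimum; the
  truncation denominator is floored at 1e-300.
* **Inference.** Wald standard errors from the inverse of a
  central-difference Hessian of the analytic gradient, computed in the
  original (unstandardised) coefficient space at the optimum; 95% CIs are
  estimate ± 1.96 SE.
* **Degenerate data.** Fits whose implied `p` exceeds 0.999, or whose
  parameters run to extreme magnitudes (e.g. every respondent reporting
  exactly one drink), are flagged `boundary_suspect`.

### Backward elimination

Model selection mirrors standard survey practice: fit the full model,
remove *all* terms non-significant at level α (default 0.05) in one sweep,
refit, and repeat until every remaining term is significant. Scalar terms
use Wald z tests; the eight age dummies are tested jointly with one Wald
chi-square per predictor and kept or dropped as a block — a categorical
variable is only meaningful whole, and it is the only reading under which
a final model can retain individually non-significant bands. Constants are
never removed; if elimination empties both predictors the intercept-only
fit is returned with a warning.

## Prediction

For thresholds `t` (default 2..12 drinks), the per-occasion exceedance is
`P(Y ≥ t | Y ≥ 1)` and the expected number of days per period at or above
`t` is that probability times the respondent's drinking days `M` — the
mean of a Binomial(M, exceedance) day count. The formula is applied as
stated, with no cap when `M` is small. `conversion_table` materialises the
same quantities over a grid of (age band, gender, K, M) for calculator-style
use.

## Validation

* **Discrimination.** Last-occasion counts are binarised at cutoffs
  2..12 (`G_t = 1 iff y ≥ t`). Per cutoff, each individual's log
  exceedance probability is the predictor in a univariate logistic
  regression fitted on the training sample; both samples are scored with
  the fitted model and summarised by AUROC, computed as the Mann–Whitney
  rank statistic with midrank ties. The logistic step cannot change the
  training AUROC (it is a monotone transform) but is retained because the
  fitted score is what transports to the testing sample; if it degenerates
  (perfect separation), the raw log probability is used. Single-class
  cutoffs are reported as missing, never fabricated.
* **Calibration.** Observed risky-day counts (5+ drinks for everyone,
  4+ for women) are regressed through the origin on predicted counts.
  The slope is `Σ(obs·pred)/Σ(pred²)` with the classical no-intercept SE,
  and R² is uncentred (`1 − RSS/Σobs²`) — the standard convention for
  regression through the origin and the only definition guaranteed to lie
  in [0, 1] here. Both come from a no-constant OLS fit (statsmodels), with
  the closed forms asserted against it in tests. Classical (not robust)
  standard errors are used.
* A note on nulls: when predictions are made with *estimated* rather than
  generating coefficients, estimation noise attenuates the calibration
  slope slightly below 1 (a regression-through-origin errors-in-variables
  effect). The machinery's ground-truth check therefore scores with the
  generating coefficient set, for which the binomial day-count construction
  makes the true slope exactly 1.

## Synthetic data

The generator emulates the variable structure the model assumes, so every
pipeline stage is testable offline: covariates from configurable marginals,
`(r, p)` through the links, last-occasion counts from the zero-truncated
negative binomial (vectorised rejection of zeros) censored at 20, and day
counts drawn `Binomial(M, exceedance)` — exactly the assumption the
calibration validation tests, by construction.

Default covariate marginals are fixture choices, not estimates of any real
survey: age weights (.01, .03, .06, .15, .12, .12, .25, .17, .09) across
the nine bands, P(female) = 0.5, `K ~ 1 + Poisson(2)` truncated to 24,
`M ~ 1 + Binomial(29, 0.25)`. Two consequences worth knowing when reading
test results:

* `M` concentrates near 8, so `ln M` and `(ln M)²` are highly collinear in
  synthetic cohorts; their standard errors are large and weak true terms
  (e.g. the female effect of −0.079 in `r`, or `(ln M)²`) are often
  eliminated at n = 30,000. The age/gender block is nonetheless reliably
  removed from the `p` predictor, where it is truly absent.
* Real survey data differ in ways the generator does not emulate —
  sampling design and weights, item nonresponse, heaped self-reports
  (spikes at 6, 12, 24 drinks), and correlation between covariates.
  Passing tests therefore demonstrate correctness of the machinery under
  the model's own assumptions, not transportability of the reference
  coefficients to any particular population.

Replicated experiments (`recovery_experiment`, the elimination
operating-characteristic checks) spawn child seeds from a single base seed
via `numpy.random.SeedSequence`, making every reported simulation
deterministic end to end.

## Problem sizes

Survey-scale checks use cohorts of n = 30,000 (comparable to the ~34,000
training records behind the reference coefficients): single-cohort
recovery, 10-replicate CI-coverage, and 20-replicate elimination runs. The
validation pipeline check uses n = 20,000 with a 75/25 split. Unit tests
run at n ≤ 8,000. One full-model fit at n = 30,000 takes a few seconds on
one CPU.

## Limitations

* No survey weights in the likelihood; variance estimates assume simple
  random sampling.
* No uncertainty intervals on predictions (coefficient uncertainty is not
  propagated through the exceedance formulas).
* The model is defined only for the two gender categories the underlying
  survey items code; other values are rejected explicitly rather than
  silently dropped.
* No beverage-specific or ethanol-gram conversion: the unit is "a drink"
  as the respondent understood it.
* Individuals drinking beyond the caps (K > 24, Y > 20) are folded into
  the bounds; the model is not intended for populations of extreme
  consumers.
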