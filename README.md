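# drinkoccasion

A mechanistic statistical model of how much a person drinks on a single
drinking occasion, built for survey epidemiologists and alcohol researchers
who have only the most basic consumption items to work with: age, gender,
usual drinks per drinking day, and drinking days in the past month.

## The model

A drinking occasion is treated as a run of *mini drinking episodes*. Every
drink is an independent trial that ends the current episode with stopping
probability `p`; an occasion comprises `r` episodes. The number of drinks
`Y` consumed on an occasion is then the sum of `r` i.i.d. geometric
(failures-before-success) variables, i.e. negative binomial:

    P(Y = y | r, p) = Γ(y + r) / (Γ(r) · y!) · p^r · (1 − p)^y,
    E[Y] = r (1 − p) / p.

Each individual's `(r, p)` is linked to four survey answers — age band
(nine categories, reference 20–25), gender, usual drinks per drinking day
`K` (1–24) and drinking days in the past 30 days `M` (1–30):

    r = 1 + exp(a_r + x·b_r),        p = logistic(a_p + x·b_p),

where the design `x` holds the age dummies, a female indicator, `ln(1/K)`,
`(ln(1/K))²`, `ln M` and `(ln M)²`. Because only current drinkers are
surveyed and reports are capped at 20 drinks, estimation maximises the
zero-truncated, right-censored likelihood

    ln l_j = ln P(Y = y_j | Y ≥ 1)           (y_j < 20)
    ln l_j = ln P(Y ≥ 20 | Y ≥ 1)            (censored),

with backward elimination of non-significant terms (the eight age dummies
tested jointly as one block). From a fitted `(r, p)` the package predicts
exceedance probabilities `P(Y ≥ t | Y ≥ 1)` and expected numbers of
risky-drinking days per month, `M · P(Y ≥ t | Y ≥ 1)`, and validates them
with cutoff-wise AUROC and slope-only (through-origin) calibration
regression.

A reference coefficient set estimated on combined 2010–2011 US
general-population survey microdata ships with the package
(`CoefficientSet.reference()`).

## Worked example

```python
from drinkoccasion import CoefficientSet, DrinkerProfile, compute_params, predict_risk

coeffs = CoefficientSet.reference()
profile = DrinkerProfile(age_band="35-49", gender="female",
                         usual_drinks=3, drinking_days=20)
params = compute_params(profile, coeffs)
print(params.r, params.p)      # 5.494  0.647
risk = predict_risk(profile, coeffs, thresholds=[2, 3, 4, 5])
print(risk.expected_days[5])   # 4.72
```

Running `python examples/risk_profile.py` prints, for this respondent:

```
mini episodes per occasion  r = 5.49
stopping probability        p = 0.647

threshold   P(>= t drinks | a drinking day)   expected days/month
    2              0.805                      16.09
    3              0.581                      11.62
    4              0.384                      7.67
    5              0.236                      4.72
```

Read: on any given drinking day she has a 23.6% chance of reaching five or
more drinks, so across her 20 drinking days a month she is expected to have
about 4.7 such days. For the illustrative drinker with `r = 2, p = 0.5`,
the conditional probabilities of exactly 2, 3 and 4 drinks are 0.25, 0.167
and 0.104, and with 10 drinking days the expected 2+/3+/4+ days are 6.67,
4.17 and 2.5 — the package reproduces this whole chain (see
`tests/test_acceptance.py`).

The other example scripts exercise the full workflow on synthetic cohorts:
`examples/fit_synthetic_cohort.py` (simulate → fit → backward elimination)
and `examples/validate_model.py` (train/test split, AUROC per cutoff,
calibration slopes). A thin CLI wraps the same functions:

```sh
drinkoccasion simulate --n 10000 --seed 1 --out cohort.csv
drinkoccasion fit --cohort cohort.csv --out coeffs.json
drinkoccasion predict --age 35-49 --gender female --usual-drinks 3 --drinking-days 20
drinkoccasion validate --cohort cohort.csv --out report.json
```

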