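"""Predict one drinker's per-occasion risk from four survey answers.

Builds the worked-example respondent — a woman aged 35-49 who usually has
3 drinks per drinking day and drinks on 20 days a month — computes her
occasion-size parameters under the shipped reference coefficients, and
prints her probability of a 2+..12+ drink occasion together with the
expected number of such days per month.
"""

from drinkoccasion import CoefficientSet, DrinkerProfile, compute_params, predict_risk

coeffs = CoefficientSet.reference()
profile = DrinkerProfile(age_band="35-49", gender="female", usual_drinks=3, drinking_days=20)

params = compute_params(profile, coeffs)
print(f"mini episodes per occasion  r = {params.r:.2f}")
print(f"stopping probability        p = {params.p:.3f}")
print(f"implied mean occasion size      {params.mean:.2f} drinks\n")

risk = predict_risk(profile, coeffs, thresholds=range(2, 13))
print("threshold   P(>= t drinks | a drinking day)   expected days/month")
for t in range(2, 13):
    print(f"   {t:>2}              {risk.exceedance[t]:.3f}                      {risk.expected_days[t]:.2f}")

print(
    "\nEach row: the chance that a given drinking day reaches t drinks, and"
    "\nthat chance times her 20 drinking days = expected days at that level."
)
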