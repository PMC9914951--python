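"""Headline model outputs: exceedance probabilities and expected risky days.

Given an individual's (r, p), the probability of a y+ drink occasion is
P(Y >= y | Y >= 1); the expected number of days per period on which the
individual drinks at or above a threshold is that probability times the
number of drinking days M (the days count being binomial with M trials).
"Occasion" and "drinking day" are treated as synonymous throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .covariates import CoefficientSet, DrinkerProfile, compute_params
from .distribution import NBParams, conditional_exceedance

__all__ = ["RiskProfile", "DEFAULT_THRESHOLDS", "risk_from_params", "predict_risk", "conversion_table"]

DEFAULT_THRESHOLDS: tuple[int, ...] = tuple(range(2, 13))


@dataclass(frozen=True)
class RiskProfile:
    """Per-threshold exceedance probabilities and expected days per period."""

    exceedance: Mapping[int, float]
    expected_days: Mapping[int, float]
    period_days: int

    def to_dict(self) -> dict:
        return {
            "period_days": self.period_days,
            "exceedance": {str(t): v for t, v in self.exceedance.items()},
            "expected_days": {str(t): v for t, v in self.expected_days.items()},
        }


def _check_thresholds(thresholds: Iterable[int]) -> tuple[int, ...]:
    out = tuple(int(t) for t in thresholds)
    if not out:
        raise ValueError("threshold list must not be empty")
    for t in out:
        if not (1 <= t <= 20):
            raise ValueError(f"thresholds must lie in 1..20, got {t}")
    return out


def risk_from_params(
    params: NBParams, period_days: int, thresholds: Sequence[int] = DEFAULT_THRESHOLDS
) -> RiskProfile:
    """Risk profile for explicit (r, p) and a number of drinking days."""
    thresholds = _check_thresholds(thresholds)
    if int(period_days) != period_days or period_days < 1:
        raise ValueError(f"period_days must be a positive integer, got {period_days!r}")
    exc = {t: conditional_exceedance(t, params) for t in thresholds}
    days = {t: exc[t] * period_days for t in thresholds}
    return RiskProfile(exceedance=exc, expected_days=days, period_days=int(period_days))


def predict_risk(
    profile: DrinkerProfile,
    coeffs: CoefficientSet,
    thresholds: Sequence[int] = DEFAULT_THRESHOLDS,
) -> RiskProfile:
    """Compose the covariate links with the exceedance formula for one person;
    the binomial trial count is the profile's own drinking days M."""
    params = compute_params(profile, coeffs)
    return risk_from_params(params, profile.drinking_days, thresholds)


def conversion_table(
    coeffs: CoefficientSet,
    K_range: Sequence[int],
    M_range: Sequence[int],
    thresholds: Sequence[int] = DEFAULT_THRESHOLDS,
    age_bands: Sequence[str] = ("20-25",),
    genders: Sequence[str] = ("male", "female"),
) -> pd.DataFrame:
    """Deterministic look-up grid of exceedance and expected days over
    (age band, gender, K, M) combinations — the "automated calculator" view
    of the model."""
    K_range, M_range = list(K_range), list(M_range)
    thresholds = _check_thresholds(thresholds)
    if not K_range or not M_range or not age_bands or not genders:
        raise ValueError("conversion_table ranges must be non-empty")
    rows = []
    for band in age_bands:
        for gender in genders:
            for k in K_range:
                for m in M_range:
                    profile = DrinkerProfile(band, gender, k, m)
                    params = compute_params(profile, coeffs)
                    row = {
                        "age_band": profile.age_band,
                        "gender": profile.gender,
                        "usual_drinks": k,
                        "drinking_days": m,
                        "r": params.r,
                        "p": params.p,
                    }
                    for t in thresholds:
                        e = conditional_exceedance(t, params)
                        row[f"exceedance_{t}"] = e
                        row[f"expected_days_{t}"] = e * m
                    rows.append(row)
    return pd.DataFrame(rows)
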