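"""Model validation: cutoff-wise AUROC and slope-only calibration regression.

Two procedures assess the fitted model on held-out records:

* Last-occasion drink counts are recoded into binary indicators G_i = 1 iff
  y >= i for cutoffs i = 2..12. For each cutoff, the model-implied
  probability P(Y >= i | Y >= 1) is computed per individual, log-transformed,
  and a univariate logistic regression of G_i on the log probability is
  fitted on the training sample; both samples are scored with that fitted
  model and discrimination is summarised by the area under the ROC curve
  (Mann-Whitney rank statistic, tied scores handled by midranks).

* Observed counts of risky days (5+ drinks, and 4+ drinks for females) are
  regressed on the model-predicted counts through the origin. A slope near 1
  with high uncentred R^2 indicates calibration. The uncentred R^2
  (1 - RSS / sum(obs^2)) is the standard no-intercept convention and is the
  only definition guaranteed to stay in [0, 1] here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import statsmodels.api as sm
from scipy.stats import rankdata

from .covariates import CoefficientSet, compute_params_batch
from .distribution import batch_conditional_exceedance
from .estimation import ObservationRecord

__all__ = [
    "ValidationReport",
    "CalibrationResult",
    "binarize_outcome",
    "auroc",
    "auroc_pipeline",
    "slope_only_calibration",
    "validate_model",
]

DEFAULT_CUTOFFS: tuple[int, ...] = tuple(range(2, 13))


def binarize_outcome(y_last, cutoff: int) -> np.ndarray:
    """G_i coding: 1 iff the last-occasion count is at or above the cutoff."""
    if not (2 <= cutoff <= 12):
        raise ValueError(f"cutoff must lie in 2..12, got {cutoff!r}")
    return (np.asarray(y_last) >= cutoff).astype(int)


def auroc(scores, labels) -> float:
    """Area under the ROC curve via the Mann-Whitney rank statistic.

    Equals the probability that a random positive is scored above a random
    negative; tied scores count one half (midranks).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == 1
    n1 = int(pos.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUROC undefined: only one outcome class present")
    ranks = rankdata(scores)
    return float((ranks[pos].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


@dataclass(frozen=True)
class CalibrationResult:
    slope: float
    ci_low: float
    ci_high: float
    r_squared: float
    n: int


def slope_only_calibration(observed, predicted) -> CalibrationResult:
    """No-intercept linear regression of observed on predicted counts.

    slope = sum(obs * pred) / sum(pred^2); R^2 is uncentred; the 95% CI uses
    the classical regression-through-origin standard error.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1 or len(obs) < 2:
        raise ValueError("observed and predicted must be equal-length vectors of length >= 2")
    if np.all(pred == 0):
        raise ValueError("predicted values are all zero: degenerate regressor")
    model = sm.OLS(obs, pred[:, None]).fit()
    lo, hi = model.conf_int()[0]
    return CalibrationResult(
        slope=float(model.params[0]),
        ci_low=float(lo),
        ci_high=float(hi),
        r_squared=float(model.rsquared),  # uncentred: model has no constant
        n=len(obs),
    )


@dataclass(frozen=True)
class ValidationReport:
    """AUROC per cutoff (train, test) plus calibration per day-count outcome."""

    auroc_by_cutoff: Mapping[int, tuple[float | None, float | None]]
    calibration: Mapping[str, CalibrationResult]
    n_train: int
    n_test: int

    def to_dict(self) -> dict:
        return {
            "n_train": self.n_train,
            "n_test": self.n_test,
            "auroc_by_cutoff": {
                str(c): {"train": tr, "test": te} for c, (tr, te) in self.auroc_by_cutoff.items()
            },
            "calibration": {
                label: {
                    "slope": res.slope,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "r_squared": res.r_squared,
                    "n": res.n,
                }
                for label, res in self.calibration.items()
            },
        }


def _exceedance_batch(r: np.ndarray, p: np.ndarray, threshold: int) -> np.ndarray:
    return batch_conditional_exceedance(r, p, threshold)


def _logistic_scores(x_train, g_train, x_test):
    """Fit G ~ ln(prob) by logistic regression on the training sample and
    score both samples. Falls back to the raw log probability when the fit
    degenerates (e.g. perfect separation) — AUROC is unchanged because the
    fitted transform is monotone."""
    Xtr = sm.add_constant(x_train)
    Xte = sm.add_constant(x_test, has_constant="add")
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(g_train, Xtr).fit(disp=0, method="bfgs", maxiter=200)
        return np.asarray(fit.predict(Xtr)), np.asarray(fit.predict(Xte))
    except Exception:
        return np.asarray(x_train, dtype=float), np.asarray(x_test, dtype=float)


def auroc_pipeline(
    train: Sequence[ObservationRecord],
    test: Sequence[ObservationRecord],
    coeffs: CoefficientSet,
    cutoffs: Sequence[int] = DEFAULT_CUTOFFS,
) -> dict[int, tuple[float | None, float | None]]:
    """Per-cutoff discrimination of the model's exceedance probabilities.

    A cutoff whose outcome is single-class in a sample yields ``None`` for
    that sample rather than a fabricated value.
    """
    r_tr, p_tr = compute_params_batch([rec.profile for rec in train], coeffs)
    r_te, p_te = compute_params_batch([rec.profile for rec in test], coeffs)
    y_tr = np.array([rec.y_last for rec in train])
    y_te = np.array([rec.y_last for rec in test])
    out: dict[int, tuple[float | None, float | None]] = {}
    for cutoff in cutoffs:
        g_tr = binarize_outcome(y_tr, cutoff)
        g_te = binarize_outcome(y_te, cutoff)
        x_tr = np.log(_exceedance_batch(r_tr, p_tr, cutoff))
        x_te = np.log(_exceedance_batch(r_te, p_te, cutoff))
        s_tr, s_te = _logistic_scores(x_tr, g_tr, x_te)
        try:
            a_tr = auroc(s_tr, g_tr)
        except ValueError:
            a_tr = None
        try:
            a_te = auroc(s_te, g_te)
        except ValueError:
            a_te = None
        out[cutoff] = (a_tr, a_te)
    return out


def _day_calibration(records, coeffs, threshold, attr):
    recs = [rec for rec in records if getattr(rec, attr) is not None]
    if len(recs) < 2:
        return None
    r, p = compute_params_batch([rec.profile for rec in recs], coeffs)
    exc = _exceedance_batch(r, p, threshold)
    predicted = exc * np.array([rec.profile.drinking_days for rec in recs])
    observed = np.array([getattr(rec, attr) for rec in recs], dtype=float)
    return slope_only_calibration(observed, predicted)


def validate_model(
    coeffs: CoefficientSet,
    train: Sequence[ObservationRecord],
    test: Sequence[ObservationRecord],
    cutoffs: Sequence[int] = DEFAULT_CUTOFFS,
) -> ValidationReport:
    """Full validation: AUROC per cutoff plus calibration of the 5+/4+ risky
    day counts on the testing sample."""
    calibration: dict[str, CalibrationResult] = {}
    cal5 = _day_calibration(test, coeffs, 5, "days5")
    if cal5 is not None:
        calibration["days_5plus"] = cal5
    cal4 = _day_calibration(test, coeffs, 4, "days4")
    if cal4 is not None:
        calibration["days_4plus"] = cal4
    return ValidationReport(
        auroc_by_cutoff=auroc_pipeline(train, test, coeffs, cutoffs),
        calibration=calibration,
        n_train=len(train),
        n_test=len(test),
    )
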