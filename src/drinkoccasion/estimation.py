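"""Maximum-likelihood fitting of the covariate-linked occasion-size model.

Each record contributes the zero-truncated likelihood of the drinks consumed
on the last drinking occasion: ln[P(Y=y)/(1-P(0))] when the count is observed
exactly, and ln[P(Y>=c)/(1-P(0))] when the report is censored at the cap c
(20 drinks). The total log likelihood lnL = sum_j ln l_j is maximised by
quasi-Newton optimisation with an analytic gradient; Wald standard errors
come from the inverse observed information (numerical Hessian of the
analytic gradient).

Model selection follows a one-sweep backward elimination: all terms that are
non-significant at level alpha are removed together and the model refitted,
until every remaining term is significant. The eight age dummies are tested
jointly (one Wald chi-square per predictor) and kept or removed as a block,
since the category is only meaningful as a whole.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, special, stats
from scipy.special import expit, gammaln, psi

from .covariates import (
    AGE_DUMMY_TERMS,
    Coefficient,
    CoefficientSet,
    DrinkerProfile,
    design_matrix,
)
from .distribution import CensorBound, censored_mass, conditional_pmf

__all__ = [
    "ObservationRecord",
    "FitResult",
    "record_log_likelihood",
    "fit_mle",
    "eliminate_terms",
]

DEFAULT_CENSOR = CensorBound(20)


@dataclass(frozen=True)
class ObservationRecord:
    """A drinker profile together with the observed outcomes.

    ``y_last`` is the number of drinks on the last drinking occasion after
    recoding (1..c); ``censored`` marks reports at the cap. ``days5`` /
    ``days4`` are the optional observed counts of days with 5+ drinks (both
    sexes) and 4+ drinks (females only) in the past 30 days.
    """

    profile: DrinkerProfile
    y_last: int
    censored: bool | None = None
    days5: int | None = None
    days4: int | None = None

    def __post_init__(self) -> None:
        c = DEFAULT_CENSOR.c
        y = self.y_last
        if int(y) != y or not (1 <= y <= c):
            raise ValueError(f"y_last must be an integer in 1..{c}, got {y!r}")
        object.__setattr__(self, "y_last", int(y))
        censored = (y == c) if self.censored is None else bool(self.censored)
        if censored and y != c:
            raise ValueError(f"censored records must have y_last == {c}, got {y}")
        object.__setattr__(self, "censored", censored)
        for name in ("days5", "days4"):
            v = getattr(self, name)
            if v is None:
                continue
            if int(v) != v or not (0 <= v <= self.profile.drinking_days):
                raise ValueError(
                    f"{name} must be an integer in 0..drinking_days"
                    f" ({self.profile.drinking_days}), got {v!r}"
                )
            object.__setattr__(self, name, int(v))


def record_log_likelihood(
    record: ObservationRecord,
    coeffs: CoefficientSet,
    censor_bound: CensorBound = DEFAULT_CENSOR,
) -> float:
    """ln l_j for one record under the given coefficient set (always <= 0)."""
    from .covariates import compute_params

    params = compute_params(record.profile, coeffs)
    if record.censored:
        value = float(np.log(censored_mass(params, censor_bound)))
    else:
        value = float(np.log(conditional_pmf(record.y_last, params)))
    if not np.isfinite(value):
        raise FloatingPointError(
            f"non-finite log likelihood for record {record!r} at r={params.r}, p={params.p}"
        )
    return value


# --------------------------------------------------------------------------
# vectorised likelihood and gradient
# --------------------------------------------------------------------------

def _nll_and_grad(theta, Xr, Xp, y, cens, c):
    kr = Xr.shape[1]
    br, bp = theta[:kr], theta[kr:]
    # soft saturation keeps the objective finite far from the optimum
    etar = np.clip(Xr @ br, -50.0, 50.0)
    etap = np.clip(Xp @ bp, -35.0, 35.0)
    r = 1.0 + np.exp(etar)
    p = expit(etap)
    logp = np.log(p)
    log1mp = np.log1p(-p)
    trunc = np.clip(-np.expm1(r * logp), 1e-300, 1.0)  # 1 - p^r
    pr = np.exp(r * logp)
    dtrunc_r = pr * logp / trunc        # d[-ln(1-p^r)]/dr
    dtrunc_p = r * np.exp((r - 1.0) * logp) / trunc

    n = len(y)
    ll = np.empty(n)
    dll_dr = np.empty(n)
    dll_dp = np.empty(n)

    unc = ~cens
    if unc.any():
        yu, ru, pu = y[unc], r[unc], p[unc]
        lpmf = (
            gammaln(yu + ru) - gammaln(ru) - gammaln(yu + 1.0)
            + ru * logp[unc] + yu * log1mp[unc]
        )
        ll[unc] = lpmf - np.log(trunc[unc])
        dll_dr[unc] = psi(yu + ru) - psi(ru) + logp[unc] + dtrunc_r[unc]
        dll_dp[unc] = ru / pu - yu / (1.0 - pu) + dtrunc_p[unc]

    if cens.any():
        rc = r[cens][:, None]
        pc = p[cens][:, None]
        grid = np.arange(c, dtype=float)[None, :]
        lg = (
            gammaln(grid + rc) - gammaln(rc) - gammaln(grid + 1.0)
            + rc * logp[cens][:, None] + grid * log1mp[cens][:, None]
        )
        f = np.exp(lg)
        cdf = f.sum(axis=1)
        surv = np.clip(1.0 - cdf, 1e-300, 1.0)
        dC_dr = (f * (psi(grid + rc) - psi(rc) + logp[cens][:, None])).sum(axis=1)
        dC_dp = (f * (rc / pc - grid / (1.0 - pc))).sum(axis=1)
        ll[cens] = np.log(surv) - np.log(trunc[cens])
        dll_dr[cens] = -dC_dr / surv + dtrunc_r[cens]
        dll_dp[cens] = -dC_dp / surv + dtrunc_p[cens]

    wr = dll_dr * (r - 1.0)          # chain rule: dr/d eta_r = exp(eta_r)
    wp = dll_dp * p * (1.0 - p)
    grad = np.concatenate([Xr.T @ wr, Xp.T @ wp])
    nll = -float(ll.sum())
    if not np.isfinite(nll) or not np.all(np.isfinite(grad)):
        return 1e12, np.zeros_like(theta)
    return nll, -grad


def _numerical_hessian(theta, args):
    """Central differences of the analytic gradient of the negative lnL."""
    k = len(theta)
    H = np.empty((k, k))
    for j in range(k):
        h = 1e-5 * max(1.0, abs(theta[j]))
        tp = theta.copy(); tp[j] += h
        tm = theta.copy(); tm[j] -= h
        _, gp = _nll_and_grad(tp, *args)
        _, gm = _nll_and_grad(tm, *args)
        H[:, j] = (gp - gm) / (2.0 * h)
    return 0.5 * (H + H.T)


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column z-scoring (constant column untouched). The raw design mixes
    indicators with squared logs up to ~12, which conditions the likelihood
    badly enough to stall quasi-Newton line searches."""
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    mu[0], sd[0] = 0.0, 1.0
    sd[sd == 0] = 1.0
    return (X - mu) / sd, mu, sd


def _to_scaled(beta: np.ndarray, mu: np.ndarray, sd: np.ndarray) -> np.ndarray:
    out = beta * sd
    out[0] = beta[0] + float(np.sum(beta[1:] * mu[1:]))
    return out


def _from_scaled(beta_s: np.ndarray, mu: np.ndarray, sd: np.ndarray) -> np.ndarray:
    out = beta_s / sd
    out[0] = beta_s[0] - float(np.sum(beta_s[1:] * mu[1:] / sd[1:]))
    return out


def _moment_start(y: np.ndarray) -> tuple[float, float]:
    """Intercept starting values from NB moment matching on the raw counts."""
    m = float(np.mean(y))
    v = float(np.var(y))
    p0 = m / v if v > m else 0.5
    p0 = float(np.clip(p0, 0.05, 0.95))
    r0 = max(m * p0 / (1.0 - p0), 1.05)
    return float(np.log(r0 - 1.0)), float(special.logit(p0))


@dataclass
class FitResult:
    """Outcome of one maximum-likelihood fit (or elimination run)."""

    coefficients: CoefficientSet
    log_likelihood: float
    converged: bool
    n_obs: int
    standard_errors: dict
    elimination_history: list = field(default_factory=list)
    message: str = ""
    boundary_suspect: bool = False
    covariance: np.ndarray | None = field(default=None, repr=False)
    param_index: list = field(default=None, repr=False)

    def wald_tests(self, block_age: bool = True) -> dict:
        """Wald p-values per testable unit: scalar terms by z-test, the age
        dummies jointly by chi-square (one block per predictor)."""
        if self.covariance is None:
            raise ValueError("fit carries no covariance matrix")
        theta = self._theta()
        out: dict[tuple[str, str], float] = {}
        for which in ("r", "p"):
            idx_by_term = {
                t: i for i, (w, t) in enumerate(self.param_index) if w == which
            }
            age_idx = [idx_by_term[t] for t in AGE_DUMMY_TERMS if t in idx_by_term]
            for term, i in idx_by_term.items():
                if term == "constant" or (block_age and term in AGE_DUMMY_TERMS):
                    continue
                se = np.sqrt(max(self.covariance[i, i], 0.0))
                z = theta[i] / se if se > 0 else np.inf
                out[(which, term)] = float(2.0 * stats.norm.sf(abs(z)))
            if block_age and age_idx:
                b = theta[age_idx]
                V = self.covariance[np.ix_(age_idx, age_idx)]
                try:
                    w = float(b @ np.linalg.solve(V, b))
                except np.linalg.LinAlgError:
                    w = float(b @ np.linalg.pinv(V) @ b)
                out[(which, "age_block")] = float(stats.chi2.sf(w, len(age_idx)))
        return out

    def _theta(self) -> np.ndarray:
        terms = {"r": self.coefficients.r_terms, "p": self.coefficients.p_terms}
        return np.array([terms[w][t].estimate for w, t in self.param_index])

    def to_dict(self) -> dict:
        return {
            "coefficients": self.coefficients.to_dict(),
            "standard_errors": self.standard_errors,
            "log_likelihood": self.log_likelihood,
            "converged": self.converged,
            "boundary_suspect": self.boundary_suspect,
            "n_obs": self.n_obs,
            "elimination_history": self.elimination_history,
            "message": self.message,
        }


def _design_arrays(records: Sequence[ObservationRecord], start: CoefficientSet):
    profiles = [rec.profile for rec in records]
    tr = start.active_terms("r")
    tp = start.active_terms("p")
    Xr = design_matrix(profiles, tr)
    Xp = design_matrix(profiles, tp)
    y = np.array([rec.y_last for rec in records], dtype=float)
    cens = np.array([rec.censored for rec in records], dtype=bool)
    return Xr, Xp, y, cens, tr, tp


def fit_mle(
    records: Sequence[ObservationRecord],
    start: CoefficientSet | None = None,
    *,
    censor_bound: CensorBound = DEFAULT_CENSOR,
    maxiter: int = 5000,
    n_restarts: int = 3,
    seed: int = 0,
) -> FitResult:
    """Maximise lnL over the active terms of ``start`` (default: full model).

    Starting intercepts come from NB moment matching on the raw counts when
    ``start`` is not given; slopes start at zero. On non-convergence the
    optimiser is restarted from jittered points; a fit that still fails is
    returned with ``converged=False`` and diagnostics in ``message``, never
    as a silent partial fit.
    """
    records = list(records)
    if start is None:
        start = CoefficientSet.full_model()
        y0 = np.array([rec.y_last for rec in records], dtype=float)
        a_r, a_p = _moment_start(y0)
        r_terms = dict(start.r_terms); r_terms["constant"] = Coefficient(a_r)
        p_terms = dict(start.p_terms); p_terms["constant"] = Coefficient(a_p)
        start = CoefficientSet(r_terms, p_terms)

    Xr, Xp, y, cens, tr, tp = _design_arrays(records, start)
    k = len(tr) + len(tp)
    if len(records) < 10 * k:
        raise ValueError(
            f"need at least {10 * k} records to fit {k} active terms, got {len(records)}"
        )
    theta0 = np.array(
        [start.r_terms[t].estimate for t in tr] + [start.p_terms[t].estimate for t in tp]
    )
    args = (Xr, Xp, y, cens, censor_bound.c)
    kr = len(tr)

    # optimize on z-scored columns; map the result back afterwards
    Xrs, mur, sdr = _standardize(Xr)
    Xps, mup, sdp = _standardize(Xp)
    args_scaled = (Xrs, Xps, y, cens, censor_bound.c)
    theta0_s = np.concatenate(
        [_to_scaled(theta0[:kr], mur, sdr), _to_scaled(theta0[kr:], mup, sdp)]
    )
    rng = np.random.default_rng(seed)

    def _ok(res) -> bool:
        # L-BFGS-B's status flag is unreliable in both directions: it can
        # report an ftol stop with a huge gradient on badly scaled seeds, or
        # an "abnormal" line-search end at a genuinely stationary point.
        # Judge convergence by the gradient itself.
        gmax = float(np.abs(res.jac).max())
        return bool(np.isfinite(res.fun) and gmax <= 1e-4 * (1.0 + abs(res.fun)))

    res = best = None
    theta_try = theta0_s
    for attempt in range(n_restarts + 1):
        res = optimize.minimize(
            _nll_and_grad, theta_try, args=args_scaled, jac=True, method="L-BFGS-B",
            options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-8, "maxcor": 50},
        )
        if best is None or res.fun < best.fun:
            best = res
        if _ok(res):
            break
        theta_try = theta0_s + rng.normal(0.0, 0.5, size=k)
    res = best
    theta = np.concatenate(
        [_from_scaled(res.x[:kr], mur, sdr), _from_scaled(res.x[kr:], mup, sdp)]
    )
    lnl = -float(res.fun)
    converged = _ok(res)

    H = _numerical_hessian(theta, args)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))

    param_index = [("r", t) for t in tr] + [("p", t) for t in tp]
    r_out: dict[str, Coefficient] = {}
    p_out: dict[str, Coefficient] = {}
    se_out: dict[str, dict[str, float]] = {"r": {}, "p": {}}
    for i, (which, term) in enumerate(param_index):
        coef = Coefficient(float(theta[i]), float(theta[i] - 1.96 * se[i]), float(theta[i] + 1.96 * se[i]))
        (r_out if which == "r" else p_out)[term] = coef
        se_out[which][term] = float(se[i])
    coeffs = CoefficientSet(r_out, p_out)

    etar = np.clip(Xr @ theta[: len(tr)], -50, 50)
    p_hat = expit(np.clip(Xp @ theta[len(tr):], -35, 35))
    boundary = bool(np.any(p_hat > 0.999) or np.any(etar < -12.0) or np.any(np.abs(theta) > 15))

    return FitResult(
        coefficients=coeffs,
        log_likelihood=lnl,
        converged=converged,
        n_obs=len(records),
        standard_errors=se_out,
        message="" if converged else f"optimizer did not converge: {res.message}",
        boundary_suspect=boundary,
        covariance=cov,
        param_index=param_index,
    )


def _drop_units(coeffs: CoefficientSet, units: Sequence[tuple[str, str]]) -> CoefficientSet:
    r_terms = dict(coeffs.r_terms)
    p_terms = dict(coeffs.p_terms)
    for which, unit in units:
        terms = r_terms if which == "r" else p_terms
        if unit == "age_block":
            for t in AGE_DUMMY_TERMS:
                terms.pop(t, None)
        else:
            terms.pop(unit, None)
    return CoefficientSet(r_terms, p_terms)


def eliminate_terms(
    records: Sequence[ObservationRecord],
    start: CoefficientSet | None = None,
    alpha: float = 0.05,
    *,
    max_sweeps: int = 25,
    **fit_kwargs,
) -> FitResult:
    """Backward elimination: repeatedly fit, drop every non-significant unit
    (scalar terms by Wald z, the age dummies as one joint block per
    predictor), and refit until all remaining terms are significant.

    Constants are never removed. If elimination empties both predictors of
    all non-constant terms, the intercept-only fit is returned with a
    warning message.
    """
    if not (0.0 < alpha <= 1.0):
        raise ValueError(f"alpha must lie in (0, 1], got {alpha!r}")
    history: list = []
    current = start
    fit: FitResult | None = None
    for sweep in range(1, max_sweeps + 1):
        fit = fit_mle(records, current, **fit_kwargs)
        if not fit.converged:
            fit.elimination_history = history
            return fit
        pvals = fit.wald_tests()
        to_remove = [unit for unit, pv in pvals.items() if pv >= alpha]
        history.append(
            {
                "sweep": sweep,
                "removed": [f"{w}:{t}" for w, t in to_remove],
                "log_likelihood": fit.log_likelihood,
            }
        )
        if not to_remove:
            break
        current = _drop_units(fit.coefficients, to_remove)
        if len(current.active_terms("r")) == 1 and len(current.active_terms("p")) == 1:
            fit = fit_mle(records, current, **fit_kwargs)
            fit.message = (fit.message + " " if fit.message else "") + (
                "elimination removed all non-constant terms; intercept-only model returned"
            )
            warnings.warn(fit.message)
            history.append({"sweep": sweep + 1, "removed": [], "log_likelihood": fit.log_likelihood})
            break
    fit.elimination_history = history
    return fit
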