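"""Negative-binomial occasion-size machinery with zero truncation and right censoring.

The number of drinks Y consumed on one drinking occasion is modelled as the
sum of ``r`` i.i.d. geometric "mini episode" counts: every drink is an
independent trial that ends the current episode with probability ``p``
(stopping), so Y counts failures before the r-th success and follows a
negative binomial distribution

    P(Y = y | r, p) = Gamma(y + r) / (Gamma(r) * y!) * p**r * (1 - p)**y .

``r`` need not be an integer (the covariate link makes it continuous), so all
probabilities are computed in log space via the log-gamma function.

Only current drinkers are observed (Y >= 1) and survey reports are capped at
an upper bound ``c`` (20 drinks by default), so the observable quantities are
the zero-truncated conditional pmf, the conditional exceedance probability
P(Y >= y | Y >= 1), and the censored tail mass P(Y >= c | Y >= 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

__all__ = [
    "NBParams",
    "CensorBound",
    "nb_pmf",
    "nb_cdf",
    "conditional_pmf",
    "conditional_exceedance",
    "censored_mass",
]


@dataclass(frozen=True)
class NBParams:
    """Parameters of one individual's occasion-size distribution.

    Parameters
    ----------
    r : float
        Number of mini drinking episodes per occasion (the NB size
        parameter). Strictly positive; the covariate link produces r > 1.
    p : float
        Per-drink probability of stopping (the NB "success" probability),
        in the open interval (0, 1).
    """

    r: float
    p: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.r) and self.r > 0):
            raise ValueError(f"r must be a positive finite real, got {self.r!r}")
        if not (0.0 < self.p < 1.0):
            raise ValueError(f"p must lie in the open interval (0, 1), got {self.p!r}")

    @property
    def mean(self) -> float:
        """Mean of the untruncated occasion size, r (1 - p) / p."""
        return self.r * (1.0 - self.p) / self.p


@dataclass(frozen=True)
class CensorBound:
    """Reporting cap applied to observed occasion sizes (drinks)."""

    c: int = 20

    def __post_init__(self) -> None:
        if int(self.c) != self.c or self.c < 2:
            raise ValueError(f"censor bound must be an integer >= 2, got {self.c!r}")


def _check_count(y, minimum: int) -> int:
    if int(y) != y or y < minimum:
        raise ValueError(f"y must be an integer >= {minimum}, got {y!r}")
    return int(y)


def _log_pmf(y, r: float, p: float):
    """Vectorised log NB pmf (failures-before-r-th-success form)."""
    y = np.asarray(y, dtype=float)
    return (
        special.gammaln(y + r)
        - special.gammaln(r)
        - special.gammaln(y + 1.0)
        + r * np.log(p)
        + y * np.log1p(-p)
    )


def _zero_trunc_norm(r: float, p: float) -> float:
    """1 - P(Y = 0) = 1 - p**r, computed stably."""
    return float(-np.expm1(r * np.log(p)))


def nb_pmf(y: int, params: NBParams) -> float:
    """P(Y = y | r, p) for a non-negative integer drink count y."""
    y = _check_count(y, minimum=0)
    return float(np.exp(_log_pmf(y, params.r, params.p)))


def nb_cdf(y: int, params: NBParams) -> float:
    """P(Y <= y | r, p) by direct summation of the pmf.

    Summation is exact at the small supports this model works with
    (bounds around 20 drinks); for very large y the sum is truncated once
    the remaining tail is below 1e-15.
    """
    y = _check_count(y, minimum=0)
    total = 0.0
    start = 0
    chunk = 100_000
    while start <= y:
        stop = min(y, start + chunk - 1)
        ys = np.arange(start, stop + 1)
        total += float(np.exp(_log_pmf(ys, params.r, params.p)).sum())
        if 1.0 - total < 1e-15:
            break
        start = stop + 1
    return min(total, 1.0)


def conditional_pmf(y: int, params: NBParams) -> float:
    """P(Y = y | r, p, Y >= 1): the zero-truncated occasion-size pmf."""
    y = _check_count(y, minimum=1)
    return nb_pmf(y, params) / _zero_trunc_norm(params.r, params.p)


def conditional_exceedance(y: int, params: NBParams) -> float:
    """P(Y >= y | r, p, Y >= 1), the probability of a y+ drink occasion.

    Equals 1 at y = 1 (the conditioning event) and is strictly decreasing
    in y.
    """
    y = _check_count(y, minimum=1)
    survival = max(1.0 - nb_cdf(y - 1, params), 0.0)
    return survival / _zero_trunc_norm(params.r, params.p)


def censored_mass(params: NBParams, bound: CensorBound = CensorBound()) -> float:
    """P(Y >= c | r, p, Y >= 1): the probability mass recorded at the cap."""
    return conditional_exceedance(bound.c, params)


def batch_conditional_exceedance(r, p, y: int) -> np.ndarray:
    """Vectorised P(Y >= y | Y >= 1) over arrays of (r, p) pairs."""
    y = _check_count(y, minimum=1)
    r = np.atleast_1d(np.asarray(r, dtype=float))[:, None]
    p = np.atleast_1d(np.asarray(p, dtype=float))[:, None]
    grid = np.arange(y, dtype=float)[None, :]
    cdf = np.exp(_log_pmf(grid, r, p)).sum(axis=1)
    trunc = -np.expm1(r[:, 0] * np.log(p[:, 0]))
    return np.clip(1.0 - cdf, 0.0, 1.0) / trunc
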