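"""Covariate coding and the links from survey responses to (r, p).

A respondent is described by four survey items: age band (9 ordered
categories, reference 20-25), gender, usual drinks per drinking day K
(1-24) and drinking days in the past 30 days M (1-30). K and M enter the
model through ln(1/K), (ln(1/K))^2, ln(M) and (ln(M))^2; age is dummy-coded
against the 20-25 band.

The two linear predictors map to the individual occasion-size parameters as

    r = 1 + exp(a_r + x b_r)          (so r > 1 always)
    p = logistic(a_p + x b_p)         (so 0 < p < 1)

Coefficient sets are stored by term *name*, never by position, so that a
term deactivated by model selection can never silently misalign the rest.
A reference coefficient set estimated on US general-population survey data
ships with the package (``CoefficientSet.reference()``).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
from scipy.special import expit, logit

from .distribution import NBParams

__all__ = [
    "AGE_BANDS",
    "REFERENCE_AGE_BAND",
    "AGE_DUMMY_TERMS",
    "TERM_ORDER",
    "DrinkerProfile",
    "DesignVector",
    "Coefficient",
    "CoefficientSet",
    "build_design",
    "compute_r",
    "compute_p",
    "compute_params",
    "design_matrix",
    "compute_params_batch",
]

AGE_BANDS = ("12-14", "15-17", "18-19", "20-25", "26-29", "30-34", "35-49", "50-64", "65+")
REFERENCE_AGE_BAND = "20-25"

_AGE_TERM_BY_BAND = {
    "12-14": "age_12_14",
    "15-17": "age_15_17",
    "18-19": "age_18_19",
    "26-29": "age_26_29",
    "30-34": "age_30_34",
    "35-49": "age_35_49",
    "50-64": "age_50_64",
    "65+": "age_65_plus",
}
AGE_DUMMY_TERMS = tuple(_AGE_TERM_BY_BAND[b] for b in AGE_BANDS if b != REFERENCE_AGE_BAND)

TERM_ORDER = ("constant",) + AGE_DUMMY_TERMS + ("female", "log_inv_k", "log_inv_k_sq", "log_m", "log_m_sq")

_AGE_YEAR_EDGES = ((12, 14), (15, 17), (18, 19), (20, 25), (26, 29), (30, 34), (35, 49), (50, 64))


def age_band_from_years(years: int) -> str:
    """Map integer age in years to the 9-category band coding."""
    if int(years) != years or years < 12:
        raise ValueError(f"age_years must be an integer >= 12, got {years!r}")
    for band, (lo, hi) in zip(AGE_BANDS, _AGE_YEAR_EDGES):
        if lo <= years <= hi:
            return band
    return "65+"


def _normalize_age_band(value) -> str:
    if isinstance(value, (int, np.integer)):
        return age_band_from_years(int(value))
    band = str(value).strip().replace("–", "-").replace("—", "-")
    if band == "65" or band.lower() in ("65+", "65plus", "65 plus"):
        band = "65+"
    if band not in AGE_BANDS:
        raise ValueError(f"age_band must be one of {AGE_BANDS} or integer years, got {value!r}")
    return band


@dataclass(frozen=True)
class DrinkerProfile:
    """One respondent's predictor set.

    ``age_band`` accepts a band label ("35-49", en-dash tolerated) or an
    integer age in years (mapped onto the 9 bands). ``usual_drinks`` (K) and
    ``drinking_days`` (M) must already satisfy the survey bounds; out-of-range
    raw values are recoded by the I/O layer, not here.
    """

    age_band: str
    gender: str
    usual_drinks: int
    drinking_days: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "age_band", _normalize_age_band(self.age_band))
        gender = str(self.gender).strip().lower()
        if gender not in ("male", "female"):
            raise ValueError(
                f"gender must be 'male' or 'female', got {self.gender!r}; "
                "the model is defined only for these two survey categories"
            )
        object.__setattr__(self, "gender", gender)
        k, m = self.usual_drinks, self.drinking_days
        if int(k) != k or not (1 <= k <= 24):
            raise ValueError(f"usual_drinks must be an integer in 1..24, got {k!r}")
        if int(m) != m or not (1 <= m <= 30):
            raise ValueError(f"drinking_days must be an integer in 1..30, got {m!r}")
        object.__setattr__(self, "usual_drinks", int(k))
        object.__setattr__(self, "drinking_days", int(m))


@dataclass(frozen=True)
class DesignVector:
    """Named design values for one profile, constant included."""

    values: Mapping[str, float]

    def as_array(self, terms: Sequence[str]) -> np.ndarray:
        return np.array([self.values[t] for t in terms], dtype=float)


def build_design(profile: DrinkerProfile) -> DesignVector:
    """Deterministic covariate transform: dummies plus the four log terms."""
    u1 = math.log(1.0 / profile.usual_drinks)
    v1 = math.log(profile.drinking_days)
    values = {t: 0.0 for t in TERM_ORDER}
    values["constant"] = 1.0
    if profile.age_band != REFERENCE_AGE_BAND:
        values[_AGE_TERM_BY_BAND[profile.age_band]] = 1.0
    values["female"] = 1.0 if profile.gender == "female" else 0.0
    values["log_inv_k"] = u1
    values["log_inv_k_sq"] = u1 * u1
    values["log_m"] = v1
    values["log_m_sq"] = v1 * v1
    return DesignVector(values)


class Coefficient(NamedTuple):
    estimate: float
    ci_low: float | None = None
    ci_high: float | None = None


def _validate_terms(terms: Mapping[str, Coefficient], which: str) -> dict[str, Coefficient]:
    out: dict[str, Coefficient] = {}
    for name, coef in terms.items():
        if name not in TERM_ORDER:
            raise ValueError(f"unknown term {name!r} in {which} predictor; known terms: {TERM_ORDER}")
        out[name] = coef if isinstance(coef, Coefficient) else Coefficient(*coef) if isinstance(coef, (tuple, list)) else Coefficient(float(coef))
    if "constant" not in out:
        raise ValueError(f"{which} predictor must include a 'constant' term")
    return out


@dataclass(frozen=True)
class CoefficientSet:
    """Named coefficients for the r and p linear predictors.

    A term is *active* iff it is present in the mapping; inactive terms
    contribute exactly zero. The constant is always active in both
    predictors.
    """

    r_terms: Mapping[str, Coefficient] = field(default_factory=dict)
    p_terms: Mapping[str, Coefficient] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "r_terms", _validate_terms(self.r_terms, "r"))
        object.__setattr__(self, "p_terms", _validate_terms(self.p_terms, "p"))

    # -- construction helpers -------------------------------------------------

    @classmethod
    def reference(cls) -> "CoefficientSet":
        """The shipped reference coefficient set (final selected model)."""
        text = resources.files("drinkoccasion.data").joinpath("reference_coefficients.json").read_text()
        return cls.from_dict(json.loads(text))

    @classmethod
    def full_model(cls, value: float = 0.0) -> "CoefficientSet":
        """All terms active in both predictors, coefficients set to ``value``."""
        terms = {t: Coefficient(value) for t in TERM_ORDER}
        return cls(dict(terms), dict(terms))

    @classmethod
    def intercept_only(cls, r_const: float = 0.0, p_const: float = 0.0) -> "CoefficientSet":
        return cls({"constant": Coefficient(r_const)}, {"constant": Coefficient(p_const)})

    @classmethod
    def from_params(cls, r: float, p: float) -> "CoefficientSet":
        """Intercept-only set forcing every individual to the given (r, p).

        Requires r > 1 because the link is r = 1 + exp(constant).
        """
        if r <= 1:
            raise ValueError("from_params requires r > 1 (link is r = 1 + exp(.))")
        return cls.intercept_only(math.log(r - 1.0), float(logit(p)))

    # -- evaluation -----------------------------------------------------------

    def active_terms(self, which: str) -> tuple[str, ...]:
        terms = self.r_terms if which == "r" else self.p_terms
        return tuple(t for t in TERM_ORDER if t in terms)

    def linear_predictor(self, which: str, design: DesignVector) -> float:
        terms = self.r_terms if which == "r" else self.p_terms
        return float(sum(c.estimate * design.values[t] for t, c in terms.items()))

    # -- serialisation --------------------------------------------------------

    def to_dict(self) -> dict:
        def block(terms: Mapping[str, Coefficient]) -> dict:
            return {
                name: {"estimate": c.estimate, "ci_low": c.ci_low, "ci_high": c.ci_high}
                for name, c in ((t, terms[t]) for t in TERM_ORDER if t in terms)
            }

        return {"r_terms": block(self.r_terms), "p_terms": block(self.p_terms)}

    @classmethod
    def from_dict(cls, data: Mapping) -> "CoefficientSet":
        def block(d: Mapping) -> dict[str, Coefficient]:
            return {
                name: Coefficient(float(v["estimate"]), v.get("ci_low"), v.get("ci_high"))
                for name, v in d.items()
            }

        return cls(block(data["r_terms"]), block(data["p_terms"]))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "CoefficientSet":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def compute_r(profile: DrinkerProfile, coeffs: CoefficientSet) -> float:
    """Number of mini episodes: r = 1 + exp(a_r + x b_r), strictly > 1."""
    return 1.0 + math.exp(coeffs.linear_predictor("r", build_design(profile)))


def compute_p(profile: DrinkerProfile, coeffs: CoefficientSet) -> float:
    """Stopping probability: logistic of the p linear predictor."""
    return float(expit(coeffs.linear_predictor("p", build_design(profile))))


def compute_params(profile: DrinkerProfile, coeffs: CoefficientSet) -> NBParams:
    return NBParams(r=compute_r(profile, coeffs), p=compute_p(profile, coeffs))


def design_matrix(profiles: Iterable[DrinkerProfile], terms: Sequence[str]) -> np.ndarray:
    """Stack design vectors for the given active terms into an (n, k) array."""
    rows = [build_design(pr).as_array(terms) for pr in profiles]
    return np.asarray(rows, dtype=float).reshape(len(rows), len(terms))


def compute_params_batch(
    profiles: Sequence[DrinkerProfile], coeffs: CoefficientSet
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised (r, p) for a collection of profiles."""
    tr = coeffs.active_terms("r")
    tp = coeffs.active_terms("p")
    br = np.array([coeffs.r_terms[t].estimate for t in tr])
    bp = np.array([coeffs.p_terms[t].estimate for t in tp])
    r = 1.0 + np.exp(design_matrix(profiles, tr) @ br)
    p = expit(design_matrix(profiles, tp) @ bp)
    return r, p
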