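"""Likelihood values, gradient correctness, MLE recovery and elimination."""

import json
import math

import numpy as np
import pytest
from drinkoccasion import (
    CoefficientSet,
    DrinkerProfile,
    ObservationRecord,
    eliminate_terms,
    fit_mle,
    record_log_likelihood,
)
from drinkoccasion.covariates import Coefficient
from drinkoccasion.estimation import _design_arrays, _nll_and_grad
from drinkoccasion.simulate import SimulationConfig, simulate_cohort
from tests.test_distribution import geometric_convolution_pmf


@pytest.fixture(scope="module")
def coeffs_half() -> CoefficientSet:
    """Intercept-only set forcing r=2, p=0.5 for every profile."""
    return CoefficientSet.from_params(2.0, 0.5)


class TestRecordLogLikelihood:
    def test_uncensored_values(self, coeffs_half):
        profile = DrinkerProfile("20-25", "male", 2, 10)
        # P(Y=1)=0.25 over truncation 0.75 -> 1/3
        assert record_log_likelihood(
            ObservationRecord(profile, 1), coeffs_half
        ) == pytest.approx(math.log(1 / 3), abs=1e-12)
        assert record_log_likelihood(
            ObservationRecord(profile, 2), coeffs_half
        ) == pytest.approx(math.log(0.25), abs=1e-12)

    def test_censored_equals_tail_mass(self, coeffs_half):
        from drinkoccasion import NBParams, censored_mass

        profile = DrinkerProfile("20-25", "male", 2, 10)
        rec = ObservationRecord(profile, 20, censored=True)
        assert record_log_likelihood(rec, coeffs_half) == pytest.approx(
            math.log(censored_mass(NBParams(2.0, 0.5))), abs=1e-12
        )

    def test_always_nonpositive(self, reference_coeffs, rng):
        cohort = simulate_cohort(SimulationConfig(n=200, seed=5))
        for rec in cohort:
            assert record_log_likelihood(rec, reference_coeffs) <= 0.0

    def test_record_validation(self):
        profile = DrinkerProfile("20-25", "male", 2, 10)
        with pytest.raises(ValueError):
            ObservationRecord(profile, 0)
        with pytest.raises(ValueError):
            ObservationRecord(profile, 21)
        with pytest.raises(ValueError):
            ObservationRecord(profile, 5, censored=True)
        with pytest.raises(ValueError):
            ObservationRecord(profile, 5, days5=11)  # exceeds drinking_days


class TestLikelihoodOracle:
    def test_total_loglik_matches_convolution_oracle(self, make_constant_cohort):
        """Sum of per-record log likelihoods against an explicit
        geometric-convolution enumeration of the pmf at integer r."""
        r_int, p = 3, 0.6
        coeffs = CoefficientSet.from_params(float(r_int), p)
        rng = np.random.default_rng(99)
        ys = np.clip(rng.integers(1, 21, size=200), 1, 20)
        cohort = make_constant_cohort(ys)

        pmf = geometric_convolution_pmf(r_int, p, 200)
        trunc = 1.0 - pmf[0]
        tail20 = 1.0 - pmf[:20].sum()
        oracle = sum(
            math.log(tail20 / trunc) if y == 20 else math.log(pmf[y] / trunc)
            for y in ys
        )
        ours = sum(record_log_likelihood(rec, coeffs) for rec in cohort)
        assert ours == pytest.approx(oracle, abs=1e-8)

    def test_analytic_gradient_matches_numeric(self):
        # heavy-tailed generating model so censored records carry real tail
        # mass (the finite-difference check is ill-conditioned when the
        # censored survival is negligible)
        cohort = simulate_cohort(
            SimulationConfig(n=400, seed=17, coeffs=CoefficientSet.from_params(6.0, 0.35))
        )
        assert any(rec.censored for rec in cohort)
        Xr, Xp, y, cens, tr, tp = _design_arrays(cohort, CoefficientSet.full_model())
        args = (Xr, Xp, y, cens, 20)
        rng = np.random.default_rng(1)
        theta = rng.normal(0, 0.05, Xr.shape[1] + Xp.shape[1])
        theta[0], theta[Xr.shape[1]] = np.log(5.0), -0.6
        _, g_ana = _nll_and_grad(theta, *args)
        g_num = np.empty_like(theta)
        h = 1e-6
        for j in range(len(theta)):
            tp, tm = theta.copy(), theta.copy()
            tp[j] += h
            tm[j] -= h
            g_num[j] = (_nll_and_grad(tp, *args)[0] - _nll_and_grad(tm, *args)[0]) / (2 * h)
        np.testing.assert_allclose(g_ana, g_num, rtol=1e-5, atol=1e-5)


class TestFitMle:
    def test_intercept_only_recovery(self):
        """Constant (r, p) data: fitted intercepts reproduce ln(r-1) and
        logit(p) of the generating values within 3 SE."""
        truth_r, truth_p = 3.0, 0.55
        config = SimulationConfig(n=6000, seed=31, coeffs=CoefficientSet.from_params(truth_r, truth_p))
        cohort = simulate_cohort(config)
        start = CoefficientSet.intercept_only()
        fit = fit_mle(cohort, start, seed=0)
        assert fit.converged
        a_r = fit.coefficients.r_terms["constant"]
        a_p = fit.coefficients.p_terms["constant"]
        se_r = fit.standard_errors["r"]["constant"]
        se_p = fit.standard_errors["p"]["constant"]
        assert abs(a_r.estimate - math.log(truth_r - 1)) < 3 * se_r
        from scipy.special import logit

        assert abs(a_p.estimate - logit(truth_p)) < 3 * se_p

    def test_optimum_beats_start_and_hessian_definite(self):
        cohort = simulate_cohort(SimulationConfig(n=3000, seed=8, coeffs=CoefficientSet.from_params(2.5, 0.5)))
        start = CoefficientSet.intercept_only()
        lnl_start = sum(record_log_likelihood(rec, start) for rec in cohort)
        fit = fit_mle(cohort, start, seed=0)
        assert fit.log_likelihood >= lnl_start
        # negative-definite Hessian of lnL <=> positive-definite covariance
        eigvals = np.linalg.eigvalsh(fit.covariance)
        assert np.all(eigvals > 0)

    def test_bitwise_reproducibility(self):
        cohort = simulate_cohort(SimulationConfig(n=1500, seed=12, coeffs=CoefficientSet.from_params(2.0, 0.5)))
        fits = [fit_mle(cohort, CoefficientSet.intercept_only(), seed=4) for _ in range(2)]
        assert json.dumps(fits[0].to_dict()) == json.dumps(fits[1].to_dict())

    def test_small_sample_guard(self, make_constant_cohort):
        cohort = make_constant_cohort([2] * 10)
        with pytest.raises(ValueError, match="records"):
            fit_mle(cohort, CoefficientSet.intercept_only())

    def test_degenerate_all_ones_flagged(self, make_constant_cohort):
        # every occasion one drink: p is driven toward the boundary
        cohort = make_constant_cohort([1] * 80)
        fit = fit_mle(cohort, CoefficientSet.intercept_only(), seed=0)
        assert fit.boundary_suspect
        from drinkoccasion.covariates import compute_p

        p_hat = compute_p(cohort[0].profile, fit.coefficients)
        assert p_hat > 0.95  # model-implied P(Y=1 | Y>=1) pushed toward 1


class TestElimination:
    @pytest.fixture(scope="class")
    def cohort_30k_slice(self):
        # moderate slice keeps the unit suite fast; the acceptance suite
        # exercises the full n=30,000 operating characteristics
        return simulate_cohort(SimulationConfig(n=8000, seed=21))

    def test_alpha_one_removes_nothing(self, cohort_30k_slice):
        full = fit_mle(cohort_30k_slice, seed=2)
        kept = eliminate_terms(cohort_30k_slice, alpha=1.0, seed=2)
        assert set(kept.coefficients.active_terms("r")) == set(full.coefficients.active_terms("r"))
        assert set(kept.coefficients.active_terms("p")) == set(full.coefficients.active_terms("p"))
        assert kept.log_likelihood == pytest.approx(full.log_likelihood, abs=1e-6)
        assert kept.elimination_history[0]["removed"] == []

    def test_constants_never_removed(self, cohort_30k_slice):
        fit = eliminate_terms(cohort_30k_slice, alpha=0.05, seed=2)
        assert "constant" in fit.coefficients.r_terms
        assert "constant" in fit.coefficients.p_terms

    def test_age_block_is_atomic(self, cohort_30k_slice):
        # the 8 age dummies are kept or removed together in each predictor
        fit = eliminate_terms(cohort_30k_slice, alpha=0.05, seed=2)
        from drinkoccasion.covariates import AGE_DUMMY_TERMS

        for terms in (fit.coefficients.r_terms, fit.coefficients.p_terms):
            n_age = sum(t in terms for t in AGE_DUMMY_TERMS)
            assert n_age in (0, len(AGE_DUMMY_TERMS))

    def test_invalid_alpha(self, cohort_30k_slice):
        with pytest.raises(ValueError):
            eliminate_terms(cohort_30k_slice, alpha=0.0)
        with pytest.raises(ValueError):
            eliminate_terms(cohort_30k_slice, alpha=1.5)
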