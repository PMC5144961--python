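"""Gompertz hazard/survival identities and interval-censored ML behaviour."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import optimize

import hemivar as hv
from hemivar.gompertz import (
    GompertzFit,
    MortalitySchedule,
    _interval_loglik,
    fit_gompertz,
    gompertz_hazard,
    gompertz_survival,
    log_alpha_beta_correlation,
    log_gompertz_survival,
)
from hemivar.synthetic import simulate_gompertz_cohort


class TestHazardSurvival:
    @pytest.mark.parametrize("alpha,beta,t,expected", [
        (0.01, 0.3, 0.0, 0.01),          # hazard at t=0 is alpha
        (0.01, 0.0, 100.0, 0.01),        # beta=0: constant hazard
        (0.001, 0.1, 10.0, 0.001 * np.e),
    ])
    def test_hazard_values(self, alpha, beta, t, expected):
        assert gompertz_hazard(alpha, beta, t) == pytest.approx(expected)

    def test_hazard_rejects_nonpositive_alpha(self):
        with pytest.raises(ValueError):
            gompertz_hazard(0.0, 0.1, 1.0)

    def test_survival_at_zero_is_one(self):
        assert gompertz_survival(0.01, 0.2, 0.0) == 1.0

    def test_beta_zero_series_limit(self):
        t = np.linspace(0.0, 200.0, 101)
        for alpha in (1e-4, 0.01, 0.1):
            diff = np.abs(gompertz_survival(alpha, 1e-12, t)
                          - np.exp(-alpha * t))
            assert diff.max() < 1e-9

    @given(alpha=st.floats(1e-6, 0.1), beta=st.floats(-0.05, 0.3))
    def test_survival_non_increasing(self, alpha, beta):
        t = np.linspace(0.0, 150.0, 1000)
        s = gompertz_survival(alpha, beta, t)
        assert s[0] == 1.0
        assert np.all(np.diff(s) <= 1e-15)


class TestFit:
    def test_parameter_recovery_large_cohort(self):
        alpha, beta = 2.8e-6, 0.17
        sch = simulate_gompertz_cohort(alpha, beta, 10 ** 4, 2.0, 150.0,
                                       seed=11)
        fit = fit_gompertz(sch)
        assert fit.converged
        assert abs(fit.beta - beta) < 3 * fit.se_beta
        assert abs(fit.log_alpha - np.log(alpha)) < 3 * fit.se_log_alpha

    def test_null_aging_rate_recovered(self):
        sch = simulate_gompertz_cohort(0.02, 0.0, 10 ** 4, 2.0, 500.0,
                                       seed=12)
        fit = fit_gompertz(sch)
        assert fit.converged
        assert abs(fit.beta) < 3 * fit.se_beta

    def test_optimum_beats_random_perturbations(self):
        sch = simulate_gompertz_cohort(1e-4, 0.12, 500, 2.0, 150.0, seed=13)
        fit = fit_gompertz(sch)
        ll_hat = _interval_loglik(fit.log_alpha, fit.beta, sch.boundaries,
                                  sch.deaths, sch.censored)
        rng = np.random.default_rng(14)
        for _ in range(100):
            la = fit.log_alpha + rng.normal(0, 0.3)
            b = fit.beta + rng.normal(0, 0.02)
            assert _interval_loglik(la, b, sch.boundaries, sch.deaths,
                                    sch.censored) <= ll_hat + 1e-8

    def test_single_interval_deaths_flagged_unidentifiable(self):
        sch = MortalitySchedule("v", np.array([0.0, 2.0, 4.0]),
                                np.array([0, 30]), censored=0)
        fit = fit_gompertz(sch)
        assert not fit.converged
        assert fit.message == "beta_unidentifiable"

    def test_empty_schedule_rejected(self):
        sch = MortalitySchedule("v", np.array([0.0]), np.array([], int),
                                censored=5)
        with pytest.raises(ValueError):
            fit_gompertz(sch)

    def test_interval_ml_approaches_exact_time_ml(self):
        # with very narrow intervals the interval likelihood converges to
        # the exact-time likelihood; compare against an independent
        # exact-time ML fit on the raw death ages
        alpha, beta, n = 5e-5, 0.15, 4000
        rng = np.random.default_rng(15)
        u = rng.uniform(size=n)
        t = np.log(1 - (beta / alpha) * np.log(u)) / beta

        def nll_exact(x):
            la, b = x
            a = np.exp(la)
            return -np.sum(la + b * t - (a / b) * np.expm1(b * t))

        exact = optimize.minimize(nll_exact, [np.log(alpha), beta],
                                  method="Nelder-Mead",
                                  options={"xatol": 1e-10, "fatol": 1e-12})
        bounds = np.arange(0.0, t.max() + 0.05, 0.05)
        deaths, _ = np.histogram(t, bins=bounds)
        sch = MortalitySchedule("v", bounds, deaths, censored=0)
        fit = fit_gompertz(sch)
        a_exact = np.exp(exact.x[0])
        assert abs(fit.alpha - a_exact) / a_exact < 0.01
        assert abs(fit.beta - exact.x[1]) / exact.x[1] < 0.01

    def test_time_rescaling_equivariance(self):
        # halving the time unit doubles numeric ages: alpha and beta per
        # new unit are both halved
        sch = simulate_gompertz_cohort(1e-4, 0.12, 3000, 2.0, 150.0, seed=16)
        fit1 = fit_gompertz(sch)
        sch2 = MortalitySchedule("v", sch.boundaries * 2.0, sch.deaths,
                                 sch.censored)
        fit2 = fit_gompertz(sch2)
        assert fit2.beta == pytest.approx(fit1.beta / 2, rel=1e-3)
        assert fit2.alpha == pytest.approx(fit1.alpha / 2, rel=1e-2)

    def test_beta_x100_exactly_proportional(self):
        sch = simulate_gompertz_cohort(1e-4, 0.12, 500, 2.0, 150.0, seed=17)
        fit = fit_gompertz(sch)
        assert fit.beta_x100 == 100.0 * fit.beta


def _fits_from_draws(la, b):
    return [GompertzFit(f"v{i}", alpha=float(np.exp(a)), beta=float(bb),
                        loglik=0.0, converged=True, n_deaths=50)
            for i, (a, bb) in enumerate(zip(la, b))]


class TestLogAlphaBetaCorrelation:
    def test_requires_three_fits(self):
        fits = _fits_from_draws([-10, -11], [0.1, 0.12])
        with pytest.raises(ValueError):
            log_alpha_beta_correlation(fits)

    def test_degenerate_duplicates_rejected(self):
        fits = _fits_from_draws([-10.0] * 4, [0.1, 0.11, 0.12, 0.13])
        with pytest.raises(ValueError, match="degenerate"):
            log_alpha_beta_correlation(fits)

    def test_ci_covers_strong_negative_correlation(self):
        rho, reps, n = -0.9, 40, 160
        cov = np.array([[0.36, rho * 0.6 * 0.02], [rho * 0.6 * 0.02, 4e-4]])
        rng = np.random.default_rng(18)
        hits = 0
        for _ in range(reps):
            z = rng.multivariate_normal([-11.0, 0.14], cov, size=n)
            res = log_alpha_beta_correlation(_fits_from_draws(z[:, 0],
                                                              z[:, 1]))
            hits += res["ci_low"] <= rho <= res["ci_high"]
        assert hits >= 0.90 * reps

    def test_null_correlation_ci_covers_zero(self):
        rng = np.random.default_rng(19)
        hits = 0
        reps = 60
        for _ in range(reps):
            la = rng.normal(-11, 0.6, 160)
            b = rng.normal(0.14, 0.02, 160)
            res = log_alpha_beta_correlation(_fits_from_draws(la, b))
            assert abs(res["r"]) < 0.35
            hits += res["ci_low"] <= 0.0 <= res["ci_high"]
        assert hits >= 0.85 * reps
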