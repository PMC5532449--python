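"""Normal-theory ML: likelihood values, closed forms, structured fits, SRMR,
Satorra-Bentler scaling."""

import numpy as np
import pytest
from scipy import optimize

import robustsem as rs
from robustsem.model import Parameterization
from robustsem.normal import _normal_objective, data_moments


class TestLoglikNormal:
    def test_standard_normal_at_zero(self):
        ll = rs.loglik_normal(np.array([[0.0]]), [0.0], [[1.0]])
        assert ll == pytest.approx(-0.5 * np.log(2 * np.pi), abs=1e-12)

    def test_independent_bivariate(self):
        ll = rs.loglik_normal(np.array([[3.0, 4.0]]), [0, 0], np.eye(2))
        assert ll == pytest.approx(-np.log(2 * np.pi) - 12.5, abs=1e-12)

    def test_saturated_closed_form(self, clean_300):
        data = clean_300.data
        ybar, S, n = data_moments(data)
        expected = -(n / 2) * (
            9 * np.log(2 * np.pi) + np.linalg.slogdet(S)[1] + 9
        )
        assert rs.loglik_normal(data, ybar, S) == pytest.approx(expected)

    def test_nonpd_sigma_raises(self):
        with pytest.raises(ValueError, match="positive definite"):
            rs.loglik_normal(np.zeros((2, 2)), [0, 0], [[1, 2], [2, 1]])


class TestSaturatedAndBaseline:
    def test_saturated_matches_numeric_optimum(self):
        rng = np.random.default_rng(3)
        data = rng.normal(size=(12, 2)) @ np.array([[1.0, 0.3], [0.0, 0.8]])
        sat = rs.fit_saturated_normal(data)

        def neg(v):
            mu = v[:2]
            L = np.array([[np.exp(v[2]), 0], [v[3], np.exp(v[4])]])
            return -rs.loglik_normal(data, mu, L @ L.T)

        res = optimize.minimize(neg, np.zeros(5), method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12,
                                         "maxiter": 20000})
        assert sat.loglik == pytest.approx(-res.fun, abs=1e-6)
        assert sat.n_params == 2 + 3

    def test_saturated_param_count_p9(self, clean_300):
        sat = rs.fit_saturated_normal(clean_300.data)
        assert sat.n_params == 54

    def test_standardized_data_loglik(self):
        rng = np.random.default_rng(0)
        raw = rng.normal(size=(60, 4))
        ybar, S, _ = data_moments(raw)
        z = (raw - ybar) @ np.linalg.inv(np.linalg.cholesky(S)).T
        sat = rs.fit_saturated_normal(z)
        n, p = z.shape
        assert sat.loglik == pytest.approx(
            -(n / 2) * p * (np.log(2 * np.pi) + 1), abs=1e-8
        )

    def test_baseline_equals_saturated_when_uncorrelated(self):
        rng = np.random.default_rng(1)
        raw = rng.normal(size=(50, 3))
        ybar, S, _ = data_moments(raw)
        z = (raw - ybar) @ np.linalg.inv(np.linalg.cholesky(S)).T
        assert rs.fit_baseline_normal(z).loglik == pytest.approx(
            rs.fit_saturated_normal(z).loglik, abs=1e-8
        )

    def test_baseline_nested_below_saturated(self, clean_300):
        base = rs.fit_baseline_normal(clean_300.data)
        sat = rs.fit_saturated_normal(clean_300.data)
        assert base.loglik <= sat.loglik + 1e-9
        assert sat.n_params - base.n_params == 36

    def test_zero_variance_column_rejected(self):
        data = np.column_stack([np.ones(20), np.arange(20.0)])
        with pytest.raises(ValueError, match="zero-variance"):
            rs.fit_baseline_normal(data)


class TestStructuredFit:
    def test_analytic_gradient_matches_numeric(self, spec_correct, clean_300):
        par = Parameterization(spec_correct)
        ybar, S, _ = data_moments(clean_300.data)
        rng = np.random.default_rng(5)
        x = par.start_vector() + 0.05 * rng.standard_normal(par.n_free)
        _, g = _normal_objective(x, par, ybar, S)
        num = np.zeros_like(g)
        for i in range(len(x)):
            e = np.zeros_like(x)
            e[i] = 1e-6
            num[i] = (
                _normal_objective(x + e, par, ybar, S)[0]
                - _normal_objective(x - e, par, ybar, S)[0]
            ) / 2e-6
        assert np.max(np.abs(g - num)) < 1e-6

    def test_population_moments_recover_truth(self, spec_correct, gen_params):
        mu0, Sigma0 = rs.implied_moments(gen_params)
        fit = rs.fit_ml_normal((mu0, Sigma0, 1000), spec_correct)
        assert fit.converged
        assert fit.discrepancy < 1e-9
        assert np.max(np.abs(fit.params.Lambda - gen_params.Lambda)) < 1e-4
        assert np.max(np.abs(fit.params.Psi - gen_params.Psi)) < 1e-4

    def test_data_and_moment_input_agree(self, spec_correct, clean_300):
        data = clean_300.data
        f1 = rs.fit_ml_normal(data, spec_correct)
        f2 = rs.fit_ml_normal(data_moments(data), spec_correct)
        assert np.max(
            np.abs(f1.extra["natural_estimates"] - f2.extra["natural_estimates"])
        ) < 1e-6

    def test_target_below_saturated(self, clean_fit_normal, clean_300):
        sat = rs.fit_saturated_normal(clean_300.data)
        T = 2 * (sat.loglik - clean_fit_normal.loglik)
        assert T >= 0

    def test_parameter_recovery_over_replications(
        self, spec_correct, gen_params
    ):
        """Mean estimate of each free loading within 0.05 of truth,
        200 clean replications at N = 500."""
        lams = []
        for r in range(200):
            data = rs.generate_clean(500, gen_params, 40000 + r).data
            fit = rs.fit_ml_normal(data, spec_correct)
            if fit.converged:
                lams.append(fit.params.Lambda)
        mean_lam = np.mean(lams, axis=0)
        free = spec_correct.loading.free
        assert len(lams) > 190
        assert np.max(np.abs(mean_lam[free] - gen_params.Lambda[free])) < 0.05

    def test_standard_errors_positive_and_aligned(self, spec_correct, clean_300):
        fit = rs.fit_ml_normal(clean_300.data, spec_correct, compute_se=True)
        assert fit.standard_errors is not None
        assert len(fit.standard_errors) == 31
        assert np.all(fit.standard_errors > 0)
        table = fit.parameter_table()
        assert list(table.columns) == ["parameter", "estimate", "se"]


class TestSrmr:
    def test_perfect_fit_zero(self):
        S = np.array([[2.0, 0.5], [0.5, 1.0]])
        assert rs.srmr(S, S) == 0.0

    def test_hand_value(self):
        val = rs.srmr(np.eye(2), np.array([[1.0, 0.5], [0.5, 1.0]]))
        assert val == pytest.approx(np.sqrt(0.25 / 3), abs=1e-12)

    def test_monotone_in_residual(self):
        S = np.eye(3)
        implied = np.eye(3)
        vals = []
        for off in (0.1, 0.2, 0.4):
            M = implied.copy()
            M[0, 1] = M[1, 0] = off
            vals.append(rs.srmr(S, M))
        assert vals[0] < vals[1] < vals[2]


class TestSatorraBentler:
    def test_normal_limit_scaling_near_one(self, spec_correct, gen_params):
        data = rs.generate_clean(4000, gen_params, 77).data
        fit = rs.fit_ml_normal(data, spec_correct)
        sat = rs.fit_saturated_normal(data)
        scaled_T, c = rs.sb_scaled_statistic(data, fit, sat)
        assert c == pytest.approx(1.0, abs=0.05)
        T = 2 * (sat.loglik - fit.loglik)
        assert scaled_T == pytest.approx(T, rel=0.05)

    def test_scale_equivariance(self, spec_correct, gen_params):
        data = rs.generate_clean(400, gen_params, 78).data
        fits = []
        for d in (data, 2.0 * data):
            fit = rs.fit_ml_normal(d, spec_correct)
            sat = rs.fit_saturated_normal(d)
            fits.append(rs.sb_scaled_statistic(d, fit, sat))
        assert fits[0][1] == pytest.approx(fits[1][1], rel=1e-3)
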