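"""Multivariate-t ML: density values, EM weights, ECME monotonicity,
structured fits, df estimation and its confidence interval."""

import numpy as np
import pytest
from scipy.stats import multivariate_t

import robustsem as rs
from robustsem.results import FitResult


def t_scale_mixture_data(n, params, df, seed):
    """t-distributed SEM data: normal factor data over a chi-square mixing
    weight (exactly multivariate-t with the model's scale structure)."""
    rng = np.random.default_rng(seed)
    base = rs.generate_clean(n, params, seed).data
    w = rng.chisquare(df, n) / df
    return base / np.sqrt(w)[:, None]


class TestLoglikT:
    def test_cauchy_at_zero(self):
        ll = rs.loglik_t(np.array([[0.0]]), [0.0], [[1.0]], df=1.0)
        assert ll == pytest.approx(np.log(1 / np.pi), abs=1e-12)

    def test_normal_limit(self, clean_300):
        data = clean_300.data
        mu = data.mean(axis=0)
        S = np.cov(data, rowvar=False)
        ll_t = rs.loglik_t(data, mu, S, df=1e6)
        ll_n = rs.loglik_normal(data, mu, S)
        assert ll_t == pytest.approx(ll_n, abs=1e-3)

    def test_matches_independent_density_oracle(self):
        rng = np.random.default_rng(9)
        data = rng.normal(size=(5, 3))
        mu = rng.normal(size=3)
        A = rng.normal(size=(3, 3))
        Sigma = A @ A.T + 0.5 * np.eye(3)
        for df in (2.5, 7.0, 40.0):
            ours = rs.loglik_t(data, mu, Sigma, df)
            oracle = multivariate_t(loc=mu, shape=Sigma, df=df).logpdf(data).sum()
            assert ours == pytest.approx(oracle, abs=1e-10)


class TestEmWeight:
    def test_hand_value(self):
        assert rs.em_weight(0.0, df=5, p=9) == pytest.approx(2.8)

    def test_normal_limit_weight_one(self):
        assert rs.em_weight(9.0, df=1e8, p=9) == pytest.approx(1.0, abs=1e-6)

    def test_monotone_decreasing_to_zero(self):
        d = np.linspace(0, 1e6, 200)
        w = rs.em_weight(d, df=5, p=9)
        assert np.all(np.diff(w) < 0)
        assert w[-1] < 1e-4


class TestSaturatedT:
    def test_param_counts_and_lrt_df(self, clean_300, spec_correct):
        sat = rs.fit_saturated_t(clean_300.data)
        assert sat.n_params == 55
        target = rs.fit_ml_t(clean_300.data, spec_correct)
        assert sat.n_params - target.n_params == 23

    def test_ecme_monotone_loglik(self, clean_300, gen_params):
        contaminated = rs.apply_outliers(clean_300, 0.10, 99)
        for data in (clean_300.data, contaminated.data):
            track = []
            rs.fit_saturated_t(data, track=track)
            diffs = np.diff(track)
            assert np.all(diffs > -1e-7 * (np.abs(track[0]) + 1))

    def test_moment_match_on_clean_data(self, clean_300):
        data = clean_300.data
        sat_t = rs.fit_saturated_t(data)
        sat_n = rs.fit_saturated_normal(data)
        assert sat_t.loglik >= sat_n.loglik - 0.5
        df = sat_t.params.df
        if df > 2:
            implied_cov = sat_t.params.Psi * df / (df - 2)
            S = np.cov(data, rowvar=False, bias=True)
            scale = np.sqrt(np.outer(np.diag(S), np.diag(S)))
            assert np.max(np.abs(implied_cov - S) / scale) < 0.05

    def test_baseline_nested_and_df(self, clean_300):
        base = rs.fit_baseline_t(clean_300.data)
        sat = rs.fit_saturated_t(clean_300.data)
        assert base.n_params == 19
        assert sat.n_params - base.n_params == 36
        assert base.loglik <= sat.loglik + 1e-6

    def test_baseline_close_to_saturated_for_independent_columns(self):
        rng = np.random.default_rng(4)
        data = rng.standard_t(df=6, size=(400, 4))
        base = rs.fit_baseline_t(data)
        sat = rs.fit_saturated_t(data)
        T = 2 * (sat.loglik - base.loglik)
        assert T < 30  # chi-square_6 noise scale


class TestStructuredT:
    def test_df_recovery_heavy_tailed_data(self, gen_params, spec_correct):
        dfs = []
        for r in range(8):
            data = t_scale_mixture_data(2000, gen_params, df=5.0, seed=60 + r)
            fit = rs.fit_ml_t(data, spec_correct)
            assert fit.converged
            dfs.append(fit.params.df)
        assert all(4.0 <= d <= 6.5 for d in dfs)

    def test_clean_data_df_at_upper_range(self, clean_300, spec_correct):
        fit = rs.fit_ml_t(clean_300.data, spec_correct)
        fit_n = rs.fit_ml_normal(clean_300.data, spec_correct)
        assert fit.params.df >= 50
        assert abs(fit.loglik - fit_n.loglik) < 0.5

    def test_fixed_large_df_reproduces_normal_fit(self, clean_300, spec_correct):
        fit_t = rs.fit_ml_t(clean_300.data, spec_correct, df_mode=1e6)
        fit_n = rs.fit_ml_normal(clean_300.data, spec_correct)
        assert np.max(np.abs(
            fit_t.extra["natural_estimates"] - fit_n.extra["natural_estimates"]
        )) < 1e-3

    def test_single_gross_outlier_robustness(self, gen_params, spec_correct):
        """One row at 100x the data scale barely moves ML-t loadings but
        moves ML-Normal loadings by a strictly larger relative amount."""
        data = rs.generate_clean(300, gen_params, 31).data
        spiked = data.copy()
        spiked[0] = 100.0 * spiked[0]
        free = spec_correct.loading.free

        def rel_change(fitfn):
            lam0 = fitfn(data).params.Lambda[free]
            lam1 = fitfn(spiked).params.Lambda[free]
            return np.max(np.abs(lam1 - lam0) / np.maximum(np.abs(lam0), 0.1))

        change_t = rel_change(lambda d: rs.fit_ml_t(d, spec_correct))
        change_n = rel_change(lambda d: rs.fit_ml_normal(d, spec_correct))
        assert change_t < 0.10
        assert change_n > change_t


class TestDfConfidenceInterval:
    def _dummy_fit(self, df, se):
        params = rs.ParameterSet(
            nu=np.zeros(1), Lambda=np.eye(1), alpha=np.zeros(1),
            B=np.zeros((1, 1)), Psi=np.eye(1), Theta=np.zeros((1, 1)), df=df,
        )
        return FitResult(
            params=params, loglik=0.0, n_params=2, converged=True, n_iter=1,
            family="t", n=100, free_names=["psi[f1,f1]", "df"],
            standard_errors=np.array([0.1, se]),
        )

    def test_degenerate_zero_se(self):
        lo, hi = rs.df_confidence_interval(self._dummy_fit(24.5, 0.0))
        assert lo == hi == 24.5

    def test_symmetric_about_estimate(self):
        lo, hi = rs.df_confidence_interval(self._dummy_fit(24.5, 4.898))
        assert (lo + hi) / 2 == pytest.approx(24.5)
        assert hi - 24.5 == pytest.approx(1.959964 * 4.898, rel=1e-4)

    def test_coverage_at_known_df(self, gen_params, spec_correct):
        """Nominal 95% Wald interval covers the generating df = 5 in at
        least 88% of replications."""
        hits = 0
        total = 0
        for r in range(100):
            data = t_scale_mixture_data(2000, gen_params, df=5.0, seed=900 + r)
            fit = rs.fit_ml_t(data, spec_correct, compute_se=True)
            if not fit.converged or fit.standard_errors is None:
                continue
            lo, hi = rs.df_confidence_interval(fit)
            total += 1
            hits += lo <= 5.0 <= hi
        assert total >= 90
        assert hits / total >= 0.88

    def test_requires_se(self, clean_300, spec_correct):
        fit = rs.fit_ml_t(clean_300.data, spec_correct)
        with pytest.raises(ValueError, match="standard errors"):
            rs.df_confidence_interval(fit)
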