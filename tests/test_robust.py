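"""Huber weights, the consistency constant, robust moments, and the
two-stage robust fit."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import robustsem as rs
from robustsem.normal import data_moments


class TestMahalanobis:
    def test_euclidean_case(self):
        y = np.zeros(9)
        y[0], y[1] = 3.0, 4.0
        assert rs.mahalanobis_distance(y, np.zeros(9), np.eye(9)) == pytest.approx(5.0)

    def test_zero_at_center(self):
        mu = np.array([1.0, -2.0])
        assert rs.mahalanobis_distance(mu, mu, np.eye(2)) == 0.0

    def test_matches_solve_oracle(self):
        rng = np.random.default_rng(2)
        A = rng.normal(size=(4, 4))
        Sigma = A @ A.T + np.eye(4)
        y = rng.normal(size=4)
        mu = rng.normal(size=4)
        oracle = np.sqrt((y - mu) @ np.linalg.solve(Sigma, y - mu))
        assert rs.mahalanobis_distance(y, mu, Sigma) == pytest.approx(
            oracle, abs=1e-12
        )


class TestHuberWeight:
    @pytest.mark.parametrize(
        "d,u,expected", [(0.5, 1.0, 1.0), (2.0, 1.0, 0.5), (1.0, 1.0, 1.0)]
    )
    def test_piecewise_values(self, d, u, expected):
        assert rs.huber_w1(d, u) == expected

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        d=st.floats(0.0, 1e6),
        u=st.floats(1e-3, 1e3),
    )
    def test_in_unit_interval_and_continuous(self, d, u):
        w = rs.huber_w1(d, u)
        assert 0.0 < w <= 1.0
        if d <= u:
            assert w == 1.0


class TestTauConstant:
    def test_no_downweighting_gives_one(self):
        assert rs.tau_constant(9, 0.0) == 1.0

    def test_monotone_nonincreasing_in_phi(self):
        taus = [rs.tau_constant(9, phi) for phi in (0.0, 0.05, 0.1, 0.25)]
        assert all(a >= b for a, b in zip(taus, taus[1:]))
        assert taus[-1] < 1.0

    def test_unbiasedness_under_clean_normality(self, gen_params):
        """Mean TSR scatter over clean-normal replications within 2% of the
        generating covariance elementwise."""
        _, Sigma0 = rs.implied_moments(gen_params)
        config = rs.HuberConfig.for_p(9, 0.10)
        acc = np.zeros_like(Sigma0)
        reps = 300
        for r in range(reps):
            data = rs.generate_clean(500, gen_params, 70000 + r).data
            _, S_hat, _, _ = rs.tsr_moments(data, config)
            acc += S_hat
        acc /= reps
        denom = np.sqrt(np.outer(np.diag(Sigma0), np.diag(Sigma0)))
        assert np.max(np.abs(acc - Sigma0) / denom) < 0.02


class TestTsrMoments:
    def test_phi_zero_reduces_to_sample_moments(self, clean_300):
        config = rs.HuberConfig.for_p(9, 0.0)
        mu, S, w, _ = rs.tsr_moments(clean_300.data, config)
        ybar, S_ml, _ = data_moments(clean_300.data)
        assert np.allclose(mu, ybar, atol=1e-10)
        assert np.allclose(S, S_ml, atol=1e-10)
        assert np.all(w == 1.0)

    def test_consistency_on_clean_data(self, gen_params):
        data = rs.generate_clean(500, gen_params, 123).data
        config = rs.HuberConfig.for_p(9, 0.10)
        _, S_hat, _, _ = rs.tsr_moments(data, config)
        _, S_ml, _ = data_moments(data)
        denom = np.sqrt(np.outer(np.diag(S_ml), np.diag(S_ml)))
        assert np.max(np.abs(S_hat - S_ml) / denom) < 0.05

    def test_downweights_scaled_rows(self, gen_params):
        clean = rs.generate_clean(400, gen_params, 124).data
        bad = clean.copy()
        bad[:20] *= 10.0
        _, S_clean, _ = data_moments(clean)
        _, S_raw, _ = data_moments(bad)
        config = rs.HuberConfig.for_p(9, 0.10)
        _, S_tsr, w, _ = rs.tsr_moments(bad, config)
        err_tsr = np.linalg.norm(S_tsr - S_clean)
        err_raw = np.linalg.norm(S_raw - S_clean)
        assert err_tsr < err_raw
        # weight monotonicity: rows sorted by distance have non-increasing w1
        mu, S_hat, w, _ = rs.tsr_moments(bad, config)
        d = rs.mahalanobis_distance(bad, mu, S_hat)
        order = np.argsort(d)
        assert np.all(np.diff(w[order]) <= 1e-12)


class TestFitTsr:
    def test_reduction_to_ml_normal_at_phi_zero(self, clean_300, spec_correct):
        f_tsr = rs.fit_tsr(clean_300.data, spec_correct,
                           rs.HuberConfig.for_p(9, 0.0))
        f_mln = rs.fit_ml_normal(clean_300.data, spec_correct)
        assert np.max(np.abs(
            f_tsr.extra["natural_estimates"] - f_mln.extra["natural_estimates"]
        )) < 1e-8

    def test_breakdown_boundedness(self, gen_params, spec_correct):
        """With 10% of rows scaled by growing h, TSR loadings stay bounded
        while ML-Normal factor variances grow without bound."""
        base = rs.generate_clean(400, gen_params, 321).data
        free = spec_correct.loading.free
        lam_ref = rs.fit_tsr(base, spec_correct).params.Lambda[free]
        psi_n = []
        for h in (5.0, 20.0, 100.0):
            bad = base.copy()
            bad[:40] *= h
            f_tsr = rs.fit_tsr(bad, spec_correct)
            lam = f_tsr.params.Lambda[free]
            assert np.max(np.abs(lam - lam_ref)) < 0.5
            f_n = rs.fit_ml_normal(bad, spec_correct)
            psi_n.append(np.trace(f_n.params.Psi))
        assert psi_n[0] < psi_n[1] < psi_n[2]
        assert psi_n[2] > 100 * psi_n[0] / 25  # grows roughly like h^2

    def test_robust_estimates_near_truth_under_contamination(
        self, gen_params, spec_correct
    ):
        """Bad influential rows inflate the normal-theory factor covariance
        severely; the Huber-weighted and t-based fits stay near the truth."""
        traces = []
        for r in range(5):
            sample = rs.generate_clean(500, gen_params, 700 + r)
            bad = rs.apply_influential(sample, 0.10, 800 + r)
            traces.append((
                np.trace(rs.fit_ml_normal(bad.data, spec_correct).params.Psi),
                np.trace(rs.fit_ml_t(bad.data, spec_correct).params.Psi),
                np.trace(rs.fit_tsr(bad.data, spec_correct).params.Psi),
            ))
        tn, tt, tr = np.mean(traces, axis=0)
        truth = np.trace(gen_params.Psi)
        assert tn > truth + 1.0
        assert abs(tt - truth) < 0.5 * abs(tn - truth)
        assert abs(tr - truth) < 0.5 * abs(tn - truth)
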