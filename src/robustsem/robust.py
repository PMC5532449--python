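"""Two-stage robust (TSR) estimation with Huber-type case weights.

Stage 1 estimates robust means and covariances by a fixed-point iteration:

    mu    = sum w1(d_i) y_i / sum w1(d_i)
    Sigma = (1/n) sum w2(d_i) (y_i - mu)(y_i - mu)'

with d_i the Mahalanobis distance of case i from the current estimates,
w1(d) = 1 for d <= u and u/d beyond, w2(d) = w1(d)^2 / tau, u^2 the
(1 - phi) quantile of chi-square_p, and tau the consistency constant making
the weighted scatter unbiased for Sigma under uncontaminated normality.
phi is the theoretical proportion of cases downweighted.

Stage 2 feeds the robust moments into the normal-theory structured fit.
The stage-2 likelihood-ratio statistic is reported uncorrected (no
residual-based adjustment), so TSR fit statistics are indicative rather
than formally calibrated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, stats

from .model import ModelSpec
from .normal import _as_matrix, fit_ml_normal
from .results import FitResult

__all__ = [
    "HuberConfig",
    "mahalanobis_distance",
    "huber_w1",
    "tau_constant",
    "tsr_moments",
    "fit_tsr",
]


def tau_constant(p: int, phi: float) -> float:
    """Consistency constant tau = E[w1(d)^2 d^2] / p under d^2 ~ chi2_p.

    Evaluated in closed form: E[d^2 1(d<=u)] = p F_{p+2}(u^2) and the tail
    contributes u^2 (1 - F_p(u^2)).  tau = 1 when phi = 0 and decreases as
    more mass is downweighted.
    """
    if not 0 <= phi < 1:
        raise ValueError("phi must be in [0, 1)")
    if phi == 0:
        return 1.0
    u2 = stats.chi2.ppf(1.0 - phi, p)
    body = p * stats.chi2.cdf(u2, p + 2)
    tail = u2 * (1.0 - stats.chi2.cdf(u2, p))
    return float((body + tail) / p)


@dataclass
class HuberConfig:
    """Huber-weight configuration for p variables.

    ``phi`` is the theoretical downweighting proportion; ``u`` the distance
    cutoff with u^2 the (1 - phi) quantile of chi-square_p; ``tau`` the
    consistency constant.  Use :meth:`for_p` to construct from (p, phi).
    """

    phi: float
    u: float
    tau: float

    @classmethod
    def for_p(cls, p: int, phi: float = 0.10) -> "HuberConfig":
        if not 0 <= phi < 1:
            raise ValueError("phi must be in [0, 1)")
        u = np.inf if phi == 0 else float(np.sqrt(stats.chi2.ppf(1 - phi, p)))
        return cls(phi=phi, u=u, tau=tau_constant(p, phi))


def mahalanobis_distance(y, mu, Sigma):
    """Unsquared Mahalanobis distance sqrt((y-mu)' Sigma^-1 (y-mu)).

    ``y`` may be a single p-vector or an n x p matrix (one distance per row).
    """
    y = np.asarray(y, dtype=float)
    single = y.ndim == 1
    Y = np.atleast_2d(y)
    mu = np.asarray(mu, dtype=float)
    try:
        L = linalg.cholesky(np.asarray(Sigma, float), lower=True)
    except linalg.LinAlgError as exc:
        raise ValueError("Sigma must be positive definite") from exc
    z = linalg.solve_triangular(L, (Y - mu).T, lower=True)
    d = np.sqrt(np.einsum("ij,ij->j", z, z))
    return float(d[0]) if single else d


def huber_w1(d, u):
    """Huber weight: 1 for d <= u, u/d beyond; continuous at d = u."""
    if not u > 0:
        raise ValueError("u must be positive")
    d = np.asarray(d, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(d <= u, 1.0, u / np.where(d > 0, d, 1.0))
    return w if w.ndim else float(w)


def tsr_moments(
    data,
    config: HuberConfig,
    max_iter: int = 200,
    tol: float = 1e-9,
):
    """Huber-weighted mean and covariance by fixed-point iteration.

    Starts from coordinatewise medians and a MAD-scaled diagonal scatter.
    Returns ``(mu_hat, Sigma_hat, weights, n_iter)`` with ``weights`` the
    final w1 values for case diagnostics.
    """
    data = _as_matrix(data)
    n, p = data.shape
    if n <= p:
        raise ValueError("need n > p for robust moments")
    mu = np.median(data, axis=0)
    mad = np.median(np.abs(data - mu), axis=0) * 1.4826
    mad = np.where(mad > 0, mad, data.std(axis=0) + 1e-12)
    Sigma = np.diag(mad**2)
    converged = False
    w1 = np.ones(n)
    for it in range(1, max_iter + 1):
        d = mahalanobis_distance(data, mu, Sigma)
        w1 = huber_w1(d, config.u)
        w2 = w1**2 / config.tau
        mu_new = (w1[:, None] * data).sum(axis=0) / w1.sum()
        r = data - mu_new
        Sigma_new = (w2[:, None] * r).T @ r / n
        change = max(
            np.max(np.abs(mu_new - mu)), np.max(np.abs(Sigma_new - Sigma))
        )
        mu, Sigma = mu_new, Sigma_new
        try:
            linalg.cholesky(Sigma, lower=True)
        except linalg.LinAlgError as exc:
            raise ValueError("weighted scatter became degenerate") from exc
        if change < tol:
            converged = True
            break
    if not converged:
        import warnings

        warnings.warn("TSR fixed point did not converge within max_iter")
    return mu, Sigma, w1, it


def fit_tsr(
    data,
    spec: ModelSpec,
    config: HuberConfig | None = None,
    phi: float = 0.10,
    compute_se: bool = False,
) -> FitResult:
    """Two-stage robust fit: Huber-weighted moments, then ML-Normal on them.

    The returned FitResult carries the case weights in ``extra['weights']``;
    its likelihood and LRT are the stage-2 (uncorrected) quantities.
    """
    data = _as_matrix(data)
    n, p = data.shape
    if config is None:
        config = HuberConfig.for_p(p, phi)
    mu, Sigma, weights, n_iter = tsr_moments(data, config)
    fit = fit_ml_normal((mu, Sigma, n), spec, compute_se=compute_se)
    fit.method = "tsr"
    fit.extra["weights"] = weights
    fit.extra["huber_config"] = config
    fit.extra["stage1_iterations"] = n_iter
    return fit
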