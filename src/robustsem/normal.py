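"""Normal-theory maximum likelihood (ML-Normal) estimation.

Fits the structured model by minimizing the ML discrepancy

    F(theta) = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p
               + (ybar - mu)' Sigma^-1 (ybar - mu)

with S the sample covariance with divisor n, so that the likelihood-ratio
statistic against the saturated model equals n * F_hat exactly.  Saturated
and independence-baseline fits have closed forms.  Also provides SRMR and
the Satorra-Bentler mean-scaled statistic computed from empirical fourth
moments.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .model import (
    ModelSpec,
    ParameterSet,
    Parameterization,
    count_free_parameters,
    implied_moments,
)
from .results import FitResult

__all__ = [
    "loglik_normal",
    "fit_ml_normal",
    "fit_saturated_normal",
    "fit_baseline_normal",
    "srmr",
    "sb_scaled_statistic",
]

_MIN_FREE_VARIANCE = 1e-7


def _as_matrix(data) -> np.ndarray:
    if isinstance(data, pd.DataFrame):
        data = data.to_numpy()
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be a 2-D n x p array")
    return data


def data_moments(data):
    """Column means and covariance with divisor n."""
    data = _as_matrix(data)
    n = data.shape[0]
    ybar = data.mean(axis=0)
    r = data - ybar
    S = r.T @ r / n
    return ybar, S, n


def loglik_normal(data, mu, Sigma) -> float:
    """Sum of log multivariate-normal densities over the rows of ``data``."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    Sigma = np.atleast_2d(np.asarray(Sigma, dtype=float))
    n, p = data.shape
    try:
        L = linalg.cholesky(Sigma, lower=True)
    except linalg.LinAlgError as exc:
        raise ValueError("Sigma is not positive definite") from exc
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    z = linalg.solve_triangular(L, (data - mu).T, lower=True)
    quad = np.einsum("ij,ij->j", z, z)
    return float(-0.5 * (n * (p * np.log(2 * np.pi) + logdet) + quad.sum()))


def saturated_loglik_normal(S, n: int) -> float:
    """Closed-form maximized log-likelihood of the unconstrained model."""
    p = S.shape[0]
    sign, logdet = np.linalg.slogdet(S)
    if sign <= 0:
        raise ValueError("sample covariance is singular; need n > p")
    return -0.5 * n * (p * np.log(2 * np.pi) + logdet + p)


# ---------------------------------------------------------------------------
# Structured fit: objective, analytic gradient, chain rule


def _matrix_grads(params: ParameterSet, W: np.ndarray, dmu: np.ndarray):
    """Chain rule from (dV/dSigma, dV/dmu) to natural-scale matrix grads.

    ``W`` is the symmetric derivative of the objective with respect to Sigma
    in the trace sense dV = tr(W dSigma); ``dmu`` the derivative w.r.t. mu.
    """
    q = params.q
    A = np.linalg.inv(np.eye(q) - params.B)
    M = params.Lambda @ A
    APA = A @ params.Psi @ A.T
    Aalpha = A @ params.alpha
    dLambda = 2.0 * W @ params.Lambda @ APA + np.outer(dmu, Aalpha)
    dnu = dmu
    dalpha = M.T @ dmu
    dPsi = M.T @ W @ M
    dTheta = W
    LtWL = params.Lambda.T @ W @ params.Lambda
    dB = 2.0 * A.T @ LtWL @ APA + np.outer(M.T @ dmu, Aalpha)
    return dnu, dLambda, dalpha, dB, dPsi, dTheta


def _normal_objective(x, par: Parameterization, ybar, S, penalty=1e10):
    """ML discrepancy F and its gradient on the unconstrained scale."""
    try:
        params = par.unpack(x)
        mu, Sigma = implied_moments(params)
    except ValueError:
        return penalty, np.zeros_like(x)
    p = Sigma.shape[0]
    if not np.all(np.isfinite(Sigma)):
        return penalty, np.zeros_like(x)
    try:
        L = linalg.cholesky(Sigma, lower=True)
    except linalg.LinAlgError:
        return penalty, np.zeros_like(x)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    Sinv = linalg.cho_solve((L, True), np.eye(p))
    r = ybar - mu
    sign, logdetS = np.linalg.slogdet(S)
    F = (
        logdet
        + float(np.sum(Sinv * S))
        - logdetS
        - p
        + float(r @ Sinv @ r)
    )
    Sir = Sinv @ r
    W = Sinv - Sinv @ (S + np.outer(r, r)) @ Sinv
    dmu = -2.0 * Sir
    grads = _matrix_grads(params, W, dmu)
    g = par.grad_to_vector(x, *grads)
    return F, g


def _numeric_hessian(gradfn, x, eps=1e-5):
    k = len(x)
    H = np.empty((k, k))
    for i in range(k):
        xp = x.copy()
        xp[i] += eps
        xm = x.copy()
        xm[i] -= eps
        H[:, i] = (gradfn(xp) - gradfn(xm)) / (2 * eps)
    return 0.5 * (H + H.T)


def _natural_jacobian(par: Parameterization, x, eps=1e-6):
    k = len(x)
    J = np.empty((k, k))
    for i in range(k):
        xp = x.copy()
        xp[i] += eps
        xm = x.copy()
        xm[i] -= eps
        J[:, i] = (par.natural_vector(xp) - par.natural_vector(xm)) / (2 * eps)
    return J


def _delta_method_se(par, x, hess, extra_jac=None):
    """SEs of natural-scale parameters from the unconstrained information."""
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(hess)
    J = _natural_jacobian(par, x[: par.n_free]) if extra_jac is None else extra_jac
    k = J.shape[0]
    full = cov[:k, :k]
    var = np.einsum("ij,jk,ik->i", J, full, J)
    return np.sqrt(np.maximum(var, 0.0))


def _admissible(params: ParameterSet, par: Parameterization) -> bool:
    mu, Sigma = implied_moments(params)
    try:
        linalg.cholesky(Sigma, lower=True)
    except linalg.LinAlgError:
        return False
    if np.linalg.eigvalsh(params.Psi).min() < -1e-8:
        return False
    if np.linalg.eigvalsh(params.Theta).min() < -1e-8:
        return False
    # free variances collapsed to (numerical) zero are boundary solutions
    for idx, mat in ((par.theta_idx, params.Theta), (par.psi_idx, params.Psi)):
        for i, j in idx:
            if i == j and mat[i, j] < _MIN_FREE_VARIANCE:
                return False
    return True


def _smart_start(par: Parameterization, ybar, S) -> np.ndarray:
    """Data-informed starting values: sample means, half-variance residuals."""
    spec = par.spec
    params = spec.start_parameters()
    if spec.mean_structure:
        params.nu[par.nu_idx] = ybar[par.nu_idx]
    for i, j in par.theta_idx:
        if i == j and spec.theta.free[i, j]:
            params.Theta[i, i] = max(0.5 * S[i, i], 1e-3)
    # marker-scaled factor variance starts
    if par.psi_chol:
        Psi0 = params.Psi.copy()
        for j in range(spec.q):
            fixed = ~spec.loading.free[:, j] & (spec.loading.values[:, j] != 0)
            if fixed.any():
                i = int(np.flatnonzero(fixed)[0])
                Psi0[j, j] = max(0.5 * S[i, i], 1e-3)
        od = np.sqrt(np.outer(np.diag(Psi0), np.diag(Psi0)))
        Psi = 0.2 * od
        np.fill_diagonal(Psi, np.diag(Psi0))
        try:
            np.linalg.cholesky(Psi)
            params.Psi = Psi
        except np.linalg.LinAlgError:
            pass
    return par.pack(params)


def fit_ml_normal(
    data_or_moments,
    spec: ModelSpec,
    compute_se: bool = False,
    start=None,
    max_iter: int = 1000,
    gtol: float = 1e-7,
) -> FitResult:
    """Fit a structured SEM by normal-theory maximum likelihood.

    ``data_or_moments`` is either an n x p data matrix or a tuple
    ``(mean, covariance, n)`` with the covariance using divisor n.  The two
    input forms give identical estimates.
    """
    if isinstance(data_or_moments, tuple):
        ybar, S, n = data_or_moments
        ybar = np.asarray(ybar, dtype=float)
        S = np.asarray(S, dtype=float)
    else:
        ybar, S, n = data_moments(data_or_moments)
    p = spec.p
    if S.shape != (p, p):
        raise ValueError("covariance dimension does not match spec.p")
    sign, _ = np.linalg.slogdet(S)
    if sign <= 0:
        raise ValueError("sample covariance must be positive definite")

    par = Parameterization(spec)
    x0 = par.pack(start) if isinstance(start, ParameterSet) else (
        np.asarray(start, float) if start is not None else _smart_start(par, ybar, S)
    )

    def obj(x):
        return _normal_objective(x, par, ybar, S)

    bounds = par.bounds()
    res = optimize.minimize(
        obj,
        x0,
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": max_iter, "ftol": 1e-13, "gtol": gtol, "maxcor": 25},
    )
    if not res.success or np.max(np.abs(res.jac)) > 1e-4:
        # one restart from the pattern's own start values
        res2 = optimize.minimize(
            obj,
            par.start_vector(),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": max_iter, "ftol": 1e-13, "gtol": gtol, "maxcor": 25},
        )
        if res2.fun < res.fun:
            res = res2

    params = par.unpack(res.x)
    F_hat = float(res.fun)
    converged = bool(
        (res.success or np.max(np.abs(res.jac)) < 1e-4)
        and F_hat < 1e9
        and _admissible(params, par)
    )
    loglik = saturated_loglik_normal(S, n) - 0.5 * n * F_hat
    k = count_free_parameters(spec, "normal")
    se = None
    if compute_se and converged:
        def gradfn(x):
            return _normal_objective(x, par, ybar, S)[1] * (0.5 * n)

        H = _numeric_hessian(gradfn, res.x)
        se = _delta_method_se(par, res.x, H)
    return FitResult(
        params=params,
        loglik=float(loglik),
        n_params=k,
        converged=converged,
        n_iter=int(res.nit),
        family="normal",
        n=int(n),
        model_role="target",
        standard_errors=se,
        spec=spec,
        free_vector=res.x.copy(),
        free_names=par.free_names(),
        discrepancy=F_hat,
        sample_mean=ybar,
        sample_cov=S,
        extra={"natural_estimates": par.natural_vector(res.x)},
    )


def fit_saturated_normal(data_or_moments) -> FitResult:
    """Closed-form saturated (H1) normal fit: sample mean and covariance."""
    if isinstance(data_or_moments, tuple):
        ybar, S, n = data_or_moments
        ybar = np.asarray(ybar, float)
        S = np.asarray(S, float)
    else:
        ybar, S, n = data_moments(data_or_moments)
    p = len(ybar)
    loglik = saturated_loglik_normal(S, n)
    params = ParameterSet(
        nu=ybar,
        Lambda=np.eye(p),
        alpha=np.zeros(p),
        B=np.zeros((p, p)),
        Psi=S,
        Theta=np.zeros((p, p)),
    )
    return FitResult(
        params=params,
        loglik=float(loglik),
        n_params=p + p * (p + 1) // 2,
        converged=True,
        n_iter=0,
        family="normal",
        n=int(n),
        model_role="saturated",
        sample_mean=ybar,
        sample_cov=S,
    )


def fit_baseline_normal(data_or_moments) -> FitResult:
    """Closed-form independence baseline: free means, diagonal covariance."""
    if isinstance(data_or_moments, tuple):
        ybar, S, n = data_or_moments
        ybar = np.asarray(ybar, float)
        S = np.asarray(S, float)
    else:
        ybar, S, n = data_moments(data_or_moments)
    p = len(ybar)
    d = np.diag(S)
    if np.any(d <= 0):
        raise ValueError("zero-variance column; baseline model undefined")
    Sigma = np.diag(d)
    loglik = -0.5 * n * (p * np.log(2 * np.pi) + np.sum(np.log(d)) + p)
    params = ParameterSet(
        nu=ybar,
        Lambda=np.eye(p),
        alpha=np.zeros(p),
        B=np.zeros((p, p)),
        Psi=Sigma,
        Theta=np.zeros((p, p)),
    )
    return FitResult(
        params=params,
        loglik=float(loglik),
        n_params=2 * p,
        converged=True,
        n_iter=0,
        family="normal",
        n=int(n),
        model_role="baseline",
        sample_mean=ybar,
        sample_cov=S,
    )


def srmr(sample_cov, implied_cov) -> float:
    """Standardized root-mean-square residual (correlation metric,
    diagonal included, covariance structure only)."""
    S = np.asarray(sample_cov, float)
    Sig = np.asarray(implied_cov, float)
    p = S.shape[0]
    d = np.sqrt(np.outer(np.diag(S), np.diag(S)))
    resid = (S - Sig) / d
    iu = np.triu_indices(p)
    return float(np.sqrt(np.mean(resid[iu] ** 2)))


# ---------------------------------------------------------------------------
# Satorra-Bentler mean-scaled statistic


def _duplication_matrix(p: int) -> np.ndarray:
    """D such that vec(S) = D vech(S) for symmetric S."""
    m = p * (p + 1) // 2
    D = np.zeros((p * p, m))
    k = 0
    for i in range(p):  # np.tril_indices order
        for j in range(i + 1):
            D[i * p + j, k] = 1.0
            D[j * p + i, k] = 1.0
            k += 1
    return D


def _vech(M: np.ndarray) -> np.ndarray:
    p = M.shape[0]
    return M[np.tril_indices(p)]


def _covariance_jacobian(fit: FitResult, eps: float = 1e-6) -> np.ndarray:
    """Numeric Jacobian of vech(Sigma(x)) w.r.t. the covariance-relevant
    free parameters (pure mean parameters excluded)."""
    par = Parameterization(fit.spec)
    x = fit.free_vector
    keep = np.ones(par.n_free, dtype=bool)
    keep[par.sl["nu"]] = False
    keep[par.sl["alpha"]] = False
    cols = np.flatnonzero(keep)
    rows = fit.spec.p * (fit.spec.p + 1) // 2
    J = np.empty((rows, len(cols)))
    for a, i in enumerate(cols):
        xp = x.copy()
        xp[i] += eps
        xm = x.copy()
        xm[i] -= eps
        _, Sp = implied_moments(par.unpack(xp))
        _, Sm = implied_moments(par.unpack(xm))
        J[:, a] = (_vech(Sp) - _vech(Sm)) / (2 * eps)
    return J


def sb_scaled_statistic(
    data,
    target_fit: FitResult,
    saturated_fit: FitResult,
    weight_at: str = "sample",
):
    """Satorra-Bentler mean-scaled LRT statistic ("MLM"-style).

    Returns ``(scaled_T, scaling_factor)`` where ``scaling_factor =
    tr(U Gamma_hat) / df`` with Gamma_hat the empirical fourth-moment
    covariance of the vectorized covariance residuals and U the normal-theory
    residual weight matrix.  The normal-theory weight matrix is evaluated at
    the sample covariance by default (``weight_at="sample"``, the classical
    ADF-style convention, keeping the scaling a pure function of the sample
    moments) or at the model-implied covariance (``weight_at="fitted"``).
    The mean structure is assumed saturated (free intercepts), so only the
    covariance part contributes.
    """
    data = _as_matrix(data)
    n, p = data.shape
    T = 2.0 * (saturated_fit.loglik - target_fit.loglik)
    T = max(T, 0.0)
    df = saturated_fit.n_params - target_fit.n_params
    ybar = data.mean(axis=0)
    resid = data - ybar
    m = p * (p + 1) // 2
    # rows: vech of centered outer products
    prods = np.einsum("ni,nj->nij", resid, resid)
    il = np.tril_indices(p)
    vechs = prods[:, il[0], il[1]]
    Gamma = np.cov(vechs, rowvar=False, bias=True)

    if weight_at == "fitted":
        _, Sigma_w = target_fit.implied_moments()
    elif weight_at == "sample":
        Sigma_w = resid.T @ resid / n
    else:
        raise ValueError("weight_at must be 'sample' or 'fitted'")
    Sinv = np.linalg.inv(Sigma_w)
    D = _duplication_matrix(p)
    V = 0.5 * D.T @ np.kron(Sinv, Sinv) @ D
    Delta = _covariance_jacobian(target_fit)
    VD = V @ Delta
    try:
        middle = np.linalg.solve(Delta.T @ VD, VD.T)
    except np.linalg.LinAlgError:
        middle = np.linalg.pinv(Delta.T @ VD) @ VD.T
    U = V - VD @ middle
    c = float(np.trace(U @ Gamma)) / df
    if c <= 1e-8 or not np.isfinite(c):
        warnings.warn("degenerate fourth-moment matrix; clamping SB scaling")
        c = 1e-8
    return T / c, c
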