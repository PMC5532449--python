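"""Fit statistics and model-selection criteria.

All indices are computed from the likelihood-ratio statistic T, its degrees
of freedom, and the sample size, so they apply identically to normal-family
and t-family fits:

    RMSEA = sqrt(max(T - df, 0) / (df * n))
    CFI   = 1 - max(T - df, 0) / max(T_b - df_b, T - df, 0)
    AIC   = -2 l + 2 k,  BIC = -2 l + k ln n,  SABIC = -2 l + k ln((n+2)/24)

Population (n-free) misfit of a wrong structure is measured by fitting it
to exact population moments: F0 is the minimized ML discrepancy,
population RMSEA = sqrt(F0/df), and population CFI contrasts F0 with the
independence-baseline misfit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .model import ModelSpec, ParameterSet, count_free_parameters, implied_moments
from .normal import fit_ml_normal, srmr
from .results import FitResult

__all__ = [
    "FitIndexReport",
    "lrt",
    "rmsea",
    "cfi",
    "information_criteria",
    "compare_families",
    "population_misfit",
    "fit_index_report",
]


@dataclass
class FitIndexReport:
    """One fitted model's chi-square, fit indices and information criteria."""

    T: float
    df: int
    p_value: float
    rmsea: float
    cfi: float
    srmr: float | None
    aic: float
    bic: float
    sabic: float
    n: int
    family: str

    def summary(self) -> str:
        s = (
            f"chi2(df={self.df}, N={self.n})={self.T:.2f}, "
            f"p={self.p_value:.3f}, RMSEA={self.rmsea:.3f}, "
            f"CFI={self.cfi:.3f}"
        )
        if self.srmr is not None:
            s += f", SRMR={self.srmr:.3f}"
        return s


def lrt(target: FitResult, saturated: FitResult):
    """Likelihood-ratio statistic, df and upper-tail chi-square p-value."""
    if target.family != saturated.family:
        raise ValueError("target and saturated fits must share a family")
    if target.n != saturated.n:
        raise ValueError("fits are not on the same data")
    T = 2.0 * (saturated.loglik - target.loglik)
    if T < -1e-6:
        raise ValueError(
            f"negative LRT ({T:.3g}): the target fit beats the saturated fit"
        )
    T = max(T, 0.0)
    df = saturated.n_params - target.n_params
    p = float(stats.chi2.sf(T, df)) if df > 0 else 1.0
    return T, df, p


def rmsea(T: float, df: int, n: int, use_n_minus_1: bool = False) -> float:
    """Point-estimate RMSEA; zero whenever T <= df."""
    if df <= 0 or n <= 0:
        raise ValueError("df and n must be positive")
    denom = (n - 1) if use_n_minus_1 else n
    return float(np.sqrt(max(T - df, 0.0) / (df * denom)))


def cfi(T: float, df: int, T_baseline: float, df_baseline: int) -> float:
    """Comparative fit index, clipped to [0, 1]."""
    num = max(T - df, 0.0)
    den = max(T_baseline - df_baseline, T - df, 0.0)
    if den == 0.0:
        return 1.0
    return float(np.clip(1.0 - num / den, 0.0, 1.0))


def information_criteria(fit: FitResult):
    """(AIC, BIC, SABIC) of a converged fit; k counts df for the t family."""
    ll = fit.loglik
    k = fit.n_params
    n = fit.n
    aic = -2.0 * ll + 2.0 * k
    bic = -2.0 * ll + k * np.log(n)
    sabic = -2.0 * ll + k * np.log((n + 2.0) / 24.0)
    return float(aic), float(bic), float(sabic)


def compare_families(fit_normal: FitResult, fit_t: FitResult):
    """Per-criterion flags: does the t fit have the smaller criterion?

    Returns ``None`` when either fit failed to converge (the comparison is
    excluded from Monte Carlo summaries in that case).
    """
    if not (fit_normal.converged and fit_t.converged):
        return None
    if fit_normal.n != fit_t.n:
        raise ValueError("fits are not on the same data")
    a_n, b_n, s_n = information_criteria(fit_normal)
    a_t, b_t, s_t = information_criteria(fit_t)
    return {"aic": a_t < a_n, "bic": b_t < b_n, "sabic": s_t < s_n}


def population_misfit(spec_misspecified: ModelSpec, true_params: ParameterSet):
    """Population-level misfit of a wrong structure.

    Fits ``spec_misspecified`` to the exact moments implied by
    ``true_params`` and returns ``(F0, rmsea_pop, cfi_pop)`` where F0 is the
    minimized ML discrepancy, rmsea_pop = sqrt(F0/df), and cfi_pop
    = 1 - F0 / F0_baseline with the independence (diagonal) model as the
    population baseline.
    """
    mu0, Sigma0 = implied_moments(true_params)
    p = Sigma0.shape[0]
    sign, logdet = np.linalg.slogdet(Sigma0)
    if sign <= 0:
        raise ValueError("true implied covariance must be positive definite")
    fit = fit_ml_normal((mu0, Sigma0, 10_000), spec_misspecified, gtol=1e-10)
    F0 = max(float(fit.discrepancy), 0.0)
    n_moments = p * (p + 1) // 2 + (p if spec_misspecified.mean_structure else 0)
    df = n_moments - count_free_parameters(spec_misspecified, "normal")
    rmsea_pop = float(np.sqrt(F0 / df))
    F0_base = float(np.sum(np.log(np.diag(Sigma0))) - logdet)
    if F0 < 1e-8:
        return 0.0, 0.0, 1.0
    cfi_pop = float(np.clip(1.0 - F0 / F0_base, 0.0, 1.0)) if F0_base > 0 else 1.0
    return F0, rmsea_pop, cfi_pop


def fit_index_report(
    target: FitResult,
    saturated: FitResult,
    baseline: FitResult,
    scaled_T: float | None = None,
) -> FitIndexReport:
    """Assemble chi-square, RMSEA, CFI, SRMR (normal family with sample
    moments available) and information criteria for one fitted model.

    When ``scaled_T`` is given (a Satorra-Bentler scaled statistic), the
    indices are computed from it instead of the raw LRT.
    """
    T, df, p_value = lrt(target, saturated)
    Tb, dfb, _ = lrt(baseline, saturated)
    if scaled_T is not None:
        # scale the baseline statistic by the same relative factor
        Tb = Tb * (scaled_T / T) if T > 0 else Tb
        T = scaled_T
        p_value = float(stats.chi2.sf(T, df))
    n = target.n
    srmr_val = None
    if (
        target.family == "normal"
        and target.sample_cov is not None
        and target.spec is not None
    ):
        _, implied = target.implied_moments()
        srmr_val = srmr(target.sample_cov, implied)
    aic, bic, sabic = information_criteria(target)
    return FitIndexReport(
        T=float(T),
        df=int(df),
        p_value=float(p_value),
        rmsea=rmsea(T, df, n),
        cfi=cfi(T, df, Tb, dfb),
        srmr=srmr_val,
        aic=aic,
        bic=bic,
        sabic=sabic,
        n=int(n),
        family=target.family,
    )
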