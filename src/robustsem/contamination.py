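"""Synthetic factor-model data and its two contamination mechanisms.

Clean data are generated from the linear factor model y = nu + Lambda eta
+ e with eta = (I - B)^-1 (alpha + xi), xi ~ N(0, Psi), e ~ N(0, Theta).
Two mechanisms then modify a fixed fraction epsilon of the rows:

* **outliers** — extreme measurement error: the selected rows become
  y + h * Lambda_o xi, where Lambda_o spans (part of) the orthogonal
  complement of the loading space (Lambda' Lambda_o = 0) and h = exp(z),
  z ~ N(0, 1).  The shift leaves the projection onto the loading space
  untouched, so factor-level information is preserved while the residual
  space is inflated.
* **bad influential observations** — extreme factor scores and errors
  jointly: the selected rows are multiplied elementwise by h = exp(z),
  inflating variation in every direction.

The number of modified rows is round(epsilon * n) exactly (deterministic,
not Bernoulli), and the rows are the first round(epsilon * n) positions of
a seeded shuffle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import null_space, qr

from .model import ParameterSet, implied_moments

__all__ = [
    "ContaminatedSample",
    "generate_clean",
    "orthogonal_complement_loadings",
    "apply_outliers",
    "apply_influential",
]


@dataclass
class ContaminatedSample:
    """A generated data matrix with contamination bookkeeping."""

    data: np.ndarray
    factor_scores: np.ndarray
    modified_rows: np.ndarray
    mechanism: str
    epsilon: float
    seed: int
    h_values: np.ndarray = field(default_factory=lambda: np.empty(0))
    params: ParameterSet | None = None

    @property
    def n(self) -> int:
        return self.data.shape[0]


def generate_clean(n: int, params: ParameterSet, seed) -> ContaminatedSample:
    """Draw n clean rows from the factor model defined by ``params``.

    Factor scores xi are retained for the outlier construction.
    Reproducible: the same seed gives bitwise-identical output.
    """
    rng = np.random.default_rng(seed)
    q = params.q
    A = np.linalg.inv(np.eye(q) - params.B)
    xi = rng.multivariate_normal(np.zeros(q), params.Psi, size=n,
                                 method="svd")
    e = rng.multivariate_normal(np.zeros(params.p), params.Theta, size=n,
                                method="svd")
    eta = (params.alpha + xi) @ A.T
    y = params.nu + eta @ params.Lambda.T + e
    return ContaminatedSample(
        data=y,
        factor_scores=xi,
        modified_rows=np.empty(0, dtype=int),
        mechanism="none",
        epsilon=0.0,
        seed=int(seed) if np.isscalar(seed) else -1,
        params=params,
    )


def orthogonal_complement_loadings(
    Lambda, seed=0, scale: float | str = "mean_norm"
) -> np.ndarray:
    """q columns spanning part of the null space of Lambda'.

    The basis is a seeded rotation of an orthonormal null-space basis, so it
    is deterministic given (Lambda, seed).  Each column is rescaled: by
    default to the mean Euclidean column norm of Lambda, or to a numeric
    ``scale``.  Requires p > 2q so that q orthogonal-complement directions
    exist.
    """
    Lambda = np.asarray(Lambda, dtype=float)
    p, q = Lambda.shape
    if np.linalg.matrix_rank(Lambda) < q:
        raise ValueError("Lambda must have full column rank")
    N = null_space(Lambda.T)
    if N.shape[1] < q:
        raise ValueError(
            f"null space of Lambda' has dimension {N.shape[1]} < q={q}; "
            "need p > 2q"
        )
    rng = np.random.default_rng(seed)
    R, _ = qr(rng.standard_normal((N.shape[1], N.shape[1])))
    basis = N @ R[:, :q]
    target = (
        float(np.mean(np.linalg.norm(Lambda, axis=0)))
        if scale == "mean_norm"
        else float(scale)
    )
    basis = basis / np.linalg.norm(basis, axis=0) * target
    return basis


def _select_rows(n: int, epsilon: float, rng) -> np.ndarray:
    m = int(round(epsilon * n))
    if epsilon > 0 and m == 0:
        warnings.warn("epsilon * n rounds to zero rows; nothing modified")
    return rng.permutation(n)[:m]


def apply_outliers(
    sample: ContaminatedSample,
    epsilon: float,
    seed,
    Lambda_o: np.ndarray | None = None,
    scale: float | str = 0.75,
) -> ContaminatedSample:
    """Replace round(epsilon*n) rows by y + h * Lambda_o xi, h = exp(z).

    ``scale`` sets the Euclidean column norm of Lambda_o and hence the
    outlier magnitude.  The default 0.75 is the package's calibrated value
    for which the injected outliers reproduce the documented severity of
    the built-in study design (Mahalanobis-distance ranges and their
    downstream effect on normal-theory fit statistics); ``"mean_norm"``
    scales to the mean column norm of Lambda instead.
    """
    if sample.mechanism != "none":
        raise ValueError("sample is already contaminated")
    if sample.factor_scores is None or not len(sample.factor_scores):
        raise ValueError("sample lacks factor scores")
    if epsilon == 0:
        return replace(sample, mechanism="outlier", epsilon=0.0)
    rng = np.random.default_rng(seed)
    rows = _select_rows(sample.n, epsilon, rng)
    if Lambda_o is None:
        if sample.params is None:
            raise ValueError("need params or an explicit Lambda_o")
        Lambda_o = orthogonal_complement_loadings(
            sample.params.Lambda, seed=seed, scale=scale
        )
    h = np.exp(rng.standard_normal(len(rows)))
    data = sample.data.copy()
    shift = (sample.factor_scores[rows] @ Lambda_o.T) * h[:, None]
    data[rows] = data[rows] + shift
    return replace(
        sample,
        data=data,
        modified_rows=rows,
        mechanism="outlier",
        epsilon=float(epsilon),
        h_values=h,
    )


def apply_influential(
    sample: ContaminatedSample, epsilon: float, seed
) -> ContaminatedSample:
    """Multiply round(epsilon*n) rows elementwise by h = exp(z)."""
    if sample.mechanism != "none":
        raise ValueError("sample is already contaminated")
    if epsilon == 0:
        return replace(sample, mechanism="influential", epsilon=0.0)
    rng = np.random.default_rng(seed)
    rows = _select_rows(sample.n, epsilon, rng)
    h = np.exp(rng.standard_normal(len(rows)))
    data = sample.data.copy()
    data[rows] = data[rows] * h[:, None]
    return replace(
        sample,
        data=data,
        modified_rows=rows,
        mechanism="influential",
        epsilon=float(epsilon),
        h_values=h,
    )
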