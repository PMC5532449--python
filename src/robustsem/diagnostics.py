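"""Case-level and distributional diagnostics.

Mahalanobis distances against sample or Huber-robust moments, QQ reference
quantiles from the chi-square_p distribution, and Mardia's multivariate
kurtosis for detecting heavy tails.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .normal import _as_matrix, data_moments
from .robust import HuberConfig, mahalanobis_distance, tsr_moments

__all__ = ["DistanceReport", "distance_report", "mardia_kurtosis"]


@dataclass
class DistanceReport:
    """Per-case Mahalanobis distances with QQ reference quantiles.

    ``reference_quantiles`` are sqrt(chi-square_p) quantiles aligned with
    the sorted distances (QQ pairs on the distance scale); ``flagged`` are
    the cases whose squared distance exceeds the (1 - cutoff_phi) quantile
    of chi-square_p.
    """

    distances: np.ndarray
    reference_quantiles: np.ndarray
    flagged: np.ndarray
    cutoff: float
    p: int

    def qq_pairs(self) -> pd.DataFrame:
        order = np.argsort(self.distances)
        return pd.DataFrame(
            {
                "theoretical": self.reference_quantiles,
                "observed": self.distances[order],
                "case": order,
            }
        )

    def to_frame(self) -> pd.DataFrame:
        flag = np.zeros(len(self.distances), dtype=bool)
        flag[self.flagged] = True
        return pd.DataFrame(
            {"distance": self.distances, "flagged": flag}
        )


def distance_report(
    data, moments="sample", cutoff_phi: float = 0.05
) -> DistanceReport:
    """Mahalanobis distances of every case with QQ data and outlier flags.

    ``moments`` is ``'sample'``, an explicit ``(mu, Sigma)`` pair, or a
    :class:`HuberConfig` for robust (Huber-weighted) moment estimates.
    """
    data = _as_matrix(data)
    n, p = data.shape
    if n <= p:
        raise ValueError("need n > p")
    if isinstance(moments, HuberConfig):
        mu, Sigma, _, _ = tsr_moments(data, moments)
    elif isinstance(moments, str) and moments == "sample":
        mu, Sigma, _ = data_moments(data)
    else:
        mu, Sigma = moments
    d = mahalanobis_distance(data, mu, Sigma)
    probs = (np.arange(1, n + 1) - 0.5) / n
    ref = np.sqrt(stats.chi2.ppf(probs, p))
    if cutoff_phi <= 0:
        flagged = np.empty(0, dtype=int)
        cutoff = np.inf
    else:
        cutoff = float(np.sqrt(stats.chi2.ppf(1 - cutoff_phi, p)))
        flagged = np.flatnonzero(d > cutoff)
    return DistanceReport(
        distances=d, reference_quantiles=ref, flagged=flagged,
        cutoff=cutoff, p=p,
    )


def mardia_kurtosis(data):
    """Mardia's multivariate kurtosis b2p = mean(d^4) and its normalized
    excess against the normal-theory expectation p(p + 2)."""
    data = _as_matrix(data)
    n, p = data.shape
    if n <= p:
        raise ValueError("need n > p")
    mu, Sigma, _ = data_moments(data)
    d = mahalanobis_distance(data, mu, Sigma)
    b2p = float(np.mean(d**4))
    expected = p * (p + 2.0)
    se = np.sqrt(8.0 * p * (p + 2.0) / n)
    return b2p, float((b2p - expected) / se)
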