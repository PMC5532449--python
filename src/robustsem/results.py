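"""Container for one fitted model (any family, any role)."""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import ModelSpec, ParameterSet, implied_moments

__all__ = ["FitResult"]


@dataclass
class FitResult:
    """Estimates and bookkeeping for one fitted model.

    ``loglik`` is the maximized log-likelihood; ``n_params`` counts freely
    estimated parameters (including df for the t family).  ``model_role`` is
    'target', 'saturated' or 'baseline'.  ``discrepancy`` holds the minimized
    ML fit function for normal-family structured fits (so the LRT equals
    ``n * discrepancy``); ``standard_errors`` is None unless requested.
    """

    params: ParameterSet
    loglik: float
    n_params: int
    converged: bool
    n_iter: int
    family: str
    n: int
    model_role: str = "target"
    standard_errors: np.ndarray | None = None
    spec: ModelSpec | None = None
    free_vector: np.ndarray | None = None
    free_names: list = field(default_factory=list)
    discrepancy: float | None = None
    sample_mean: np.ndarray | None = None
    sample_cov: np.ndarray | None = None
    method: str = "ml"
    extra: dict = field(default_factory=dict)

    def implied_moments(self):
        return implied_moments(self.params, self.spec)

    @property
    def df_estimate(self) -> float:
        return self.params.df

    def parameter_table(self) -> pd.DataFrame:
        """Estimates (and SEs when available) for the free parameters."""
        if not self.free_names:
            raise ValueError("no free-parameter bookkeeping on this fit")
        est = self.extra.get("natural_estimates")
        if est is None:
            raise ValueError("no natural-scale estimates stored")
        se = (
            self.standard_errors
            if self.standard_errors is not None
            else np.full(len(est), np.nan)
        )
        return pd.DataFrame(
            {"parameter": self.free_names, "estimate": est, "se": se}
        )

    def to_report_dict(self) -> dict:
        d = {
            "family": self.family,
            "model_role": self.model_role,
            "method": self.method,
            "n": int(self.n),
            "n_params": int(self.n_params),
            "converged": bool(self.converged),
            "n_iter": int(self.n_iter),
            "loglik": float(self.loglik),
        }
        if np.isfinite(self.params.df):
            d["df_estimate"] = float(self.params.df)
        if self.free_names and "natural_estimates" in self.extra:
            d["estimates"] = {
                name: float(v)
                for name, v in zip(
                    self.free_names, self.extra["natural_estimates"]
                )
            }
            if self.standard_errors is not None:
                d["standard_errors"] = {
                    name: float(v)
                    for name, v in zip(self.free_names, self.standard_errors)
                }
        return d

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_report_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text
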