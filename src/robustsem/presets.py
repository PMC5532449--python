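"""Built-in study model: a 3-factor, 9-indicator CFA.

The generating parameter values are the ones used throughout the package's
Monte Carlo evaluation: marker loadings of 1 per factor, a 0.5 cross-loading
of item 9 on factor 1 in addition to its 1.25 primary loading on factor 3,
unit factor variances with 0.25 covariances, identity residual covariance,
and zero means.  The misspecified analysis model omits the cross-loading
(population RMSEA 0.061, population CFI 0.96 against these moments).
"""

from __future__ import annotations

import numpy as np

from .model import ModelSpec, ParameterSet, cfa_spec

__all__ = ["generating_parameters", "correct_spec", "misspecified_spec"]


def generating_parameters() -> ParameterSet:
    """Population parameter values of the 3-factor, 9-indicator model."""
    Lambda = np.zeros((9, 3))
    Lambda[:, 0] = [1.0, 0.9, 1.1, 0, 0, 0, 0, 0, 0.5]
    Lambda[:, 1] = [0, 0, 0, 1.0, 0.7, 0.55, 0, 0, 0]
    Lambda[:, 2] = [0, 0, 0, 0, 0, 0, 1.0, 1.3, 1.25]
    Psi = np.full((3, 3), 0.25)
    np.fill_diagonal(Psi, 1.0)
    return ParameterSet(
        nu=np.zeros(9),
        Lambda=Lambda,
        alpha=np.zeros(3),
        B=np.zeros((3, 3)),
        Psi=Psi,
        Theta=np.eye(9),
    )


def _spec(cross_loading: bool, mean_structure: bool) -> ModelSpec:
    items_f1 = ["y1", "y2", "y3"] + (["y9"] if cross_loading else [])
    spec = cfa_spec(
        loadings={
            "f1": items_f1,
            "f2": ["y4", "y5", "y6"],
            "f3": ["y7", "y8", "y9"],
        },
        var_names=[f"y{i}" for i in range(1, 10)],
        mean_structure=mean_structure,
    )
    return spec


def correct_spec(mean_structure: bool = True) -> ModelSpec:
    """Analysis model matching the generating structure (with the item-9
    cross-loading on factor 1)."""
    return _spec(cross_loading=True, mean_structure=mean_structure)


def misspecified_spec(mean_structure: bool = True) -> ModelSpec:
    """Analysis model omitting the item-9 cross-loading."""
    return _spec(cross_loading=False, mean_structure=mean_structure)
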