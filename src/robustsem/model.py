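"""Linear SEM model representation and model-implied moments.

A confirmatory factor / structural model for p observed variables Y and q
latent variables eta:

    Y   = nu + Lambda eta + e
    eta = alpha + B eta + xi

with cov(e) = Theta, cov(xi) = Psi, and e independent of xi.  The implied
moments of Y are

    mu    = nu + Lambda (I - B)^-1 alpha
    Sigma = Lambda (I - B)^-1 Psi (I - B)^-T Lambda^T + Theta.

``ModelSpec`` records which entries of (nu, Lambda, alpha, B, Psi, Theta)
are free and which are fixed; ``ParameterSet`` is one concrete numeric
assignment, including the degrees-of-freedom parameter of the multivariate-t
family (``df = inf`` designates the normal family).

``Parameterization`` maps the free entries to an unconstrained real vector
used by the optimizers: variances enter on the log scale, a fully free Psi
through its Cholesky factor (log diagonal), and everything else identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

__all__ = [
    "Pattern",
    "ModelSpec",
    "ParameterSet",
    "implied_moments",
    "count_free_parameters",
    "cfa_spec",
    "model_spec_from_dict",
    "model_spec_to_dict",
    "load_model_spec",
    "save_model_spec",
    "Parameterization",
]


@dataclass
class Pattern:
    """Fixed/free pattern for one parameter matrix.

    ``values`` holds fixed values where ``free`` is False and starting
    values where ``free`` is True.
    """

    values: np.ndarray
    free: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.free = np.asarray(self.free, dtype=bool)
        if self.values.shape != self.free.shape:
            raise ValueError("values and free must have the same shape")

    @classmethod
    def fixed(cls, values):
        values = np.asarray(values, dtype=float)
        return cls(values, np.zeros(values.shape, dtype=bool))

    def copy(self) -> "Pattern":
        return Pattern(self.values.copy(), self.free.copy())


def _check_symmetric_pattern(pat: Pattern, name: str) -> None:
    if not np.allclose(pat.values, pat.values.T):
        raise ValueError(f"{name} start/fixed values must be symmetric")
    if not np.array_equal(pat.free, pat.free.T):
        raise ValueError(f"{name} free pattern must be symmetric")


@dataclass
class ModelSpec:
    """Free/fixed parameter pattern of a linear SEM.

    Attributes
    ----------
    p, q : int
        Number of observed variables and latent factors.
    loading, structural, psi, theta : Pattern
        Patterns for Lambda (p x q), B (q x q), Psi (q x q), Theta (p x p).
    mean_structure : bool
        Whether intercepts are modeled (nu free, alpha by its pattern).
    nu, alpha : Pattern or None
        Patterns for the intercepts; ignored when ``mean_structure`` is off.
    identification : str
        'marker_variable' (a fixed nonzero loading per factor) or
        'unit_factor_variance' (fixed unit diagonal of Psi).
    var_names, factor_names : list of str
        Labels used in reports.
    """

    p: int
    q: int
    loading: Pattern
    structural: Pattern
    psi: Pattern
    theta: Pattern
    mean_structure: bool = True
    nu: Pattern | None = None
    alpha: Pattern | None = None
    identification: str = "marker_variable"
    var_names: list = field(default_factory=list)
    factor_names: list = field(default_factory=list)

    def __post_init__(self):
        if self.loading.values.shape != (self.p, self.q):
            raise ValueError("loading pattern must be p x q")
        if self.structural.values.shape != (self.q, self.q):
            raise ValueError("structural pattern must be q x q")
        _check_symmetric_pattern(self.psi, "psi")
        _check_symmetric_pattern(self.theta, "theta")
        if self.mean_structure:
            if self.nu is None:
                self.nu = Pattern(np.zeros(self.p), np.ones(self.p, bool))
            if self.alpha is None:
                self.alpha = Pattern.fixed(np.zeros(self.q))
        if not self.var_names:
            self.var_names = [f"y{i + 1}" for i in range(self.p)]
        if not self.factor_names:
            self.factor_names = [f"f{j + 1}" for j in range(self.q)]
        self._check_identification()

    def _check_identification(self) -> None:
        for j in range(self.q):
            col = self.loading
            marker = np.any(~col.free[:, j] & (col.values[:, j] != 0.0))
            unit_var = (not self.psi.free[j, j]) and self.psi.values[j, j] > 0
            if not (marker or unit_var):
                raise ValueError(
                    f"factor {j} lacks an identification constraint "
                    "(fixed nonzero loading or fixed factor variance)"
                )

    def start_parameters(self) -> "ParameterSet":
        """ParameterSet holding the pattern's fixed and starting values."""
        nu = self.nu.values.copy() if self.mean_structure else np.zeros(self.p)
        alpha = (
            self.alpha.values.copy() if self.mean_structure else np.zeros(self.q)
        )
        return ParameterSet(
            nu=nu,
            Lambda=self.loading.values.copy(),
            alpha=alpha,
            B=self.structural.values.copy(),
            Psi=self.psi.values.copy(),
            Theta=self.theta.values.copy(),
        )


@dataclass
class ParameterSet:
    """Concrete numeric values for all model matrices.

    ``df = inf`` designates the normal family; a finite ``df`` the
    multivariate-t family, whose implied data covariance is
    ``df / (df - 2) * Sigma`` for df > 2.
    """

    nu: np.ndarray
    Lambda: np.ndarray
    alpha: np.ndarray
    B: np.ndarray
    Psi: np.ndarray
    Theta: np.ndarray
    df: float = np.inf

    def __post_init__(self):
        self.nu = np.atleast_1d(np.asarray(self.nu, dtype=float))
        self.Lambda = np.asarray(self.Lambda, dtype=float)
        self.alpha = np.atleast_1d(np.asarray(self.alpha, dtype=float))
        self.B = np.asarray(self.B, dtype=float)
        self.Psi = np.asarray(self.Psi, dtype=float)
        self.Theta = np.asarray(self.Theta, dtype=float)
        if not np.allclose(self.Psi, self.Psi.T):
            raise ValueError("Psi must be symmetric")
        if not np.allclose(self.Theta, self.Theta.T):
            raise ValueError("Theta must be symmetric")
        if not self.df > 0:
            raise ValueError("df must be positive")

    @property
    def p(self) -> int:
        return self.Lambda.shape[0]

    @property
    def q(self) -> int:
        return self.Lambda.shape[1]

    def copy(self) -> "ParameterSet":
        return replace(
            self,
            nu=self.nu.copy(),
            Lambda=self.Lambda.copy(),
            alpha=self.alpha.copy(),
            B=self.B.copy(),
            Psi=self.Psi.copy(),
            Theta=self.Theta.copy(),
        )


def implied_moments(params: ParameterSet, spec: ModelSpec | None = None):
    """Model-implied mean vector and covariance/scale matrix.

    Returns ``(mu, Sigma)`` with ``mu = nu + Lambda (I-B)^-1 alpha`` and
    ``Sigma = Lambda (I-B)^-1 Psi (I-B)^-T Lambda^T + Theta``.  For the t
    family ``Sigma`` is the scale matrix; the implied data covariance is
    ``df/(df-2) * Sigma`` when df > 2.
    """
    q = params.q
    ImB = np.eye(q) - params.B
    try:
        A = np.linalg.inv(ImB)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "(I - B) is singular: the structural model is non-recursive "
            "or ill-specified"
        ) from exc
    M = params.Lambda @ A
    mu = params.nu + M @ params.alpha
    Sigma = M @ params.Psi @ M.T + params.Theta
    Sigma = 0.5 * (Sigma + Sigma.T)
    return mu, Sigma


def count_free_parameters(spec: ModelSpec, model_family: str = "normal") -> int:
    """Number of freely estimated parameters, including intercepts when the
    mean structure is on and one extra df parameter for the t family."""
    if model_family not in ("normal", "t"):
        raise ValueError("model_family must be 'normal' or 't'")
    k = int(spec.loading.free.sum())
    k += int(spec.structural.free.sum())
    k += int(np.triu(spec.psi.free).sum())
    k += int(np.triu(spec.theta.free).sum())
    if spec.mean_structure:
        k += int(spec.nu.free.sum())
        k += int(spec.alpha.free.sum())
    if model_family == "t":
        k += 1
    return k


# ---------------------------------------------------------------------------
# Convenience builder and (de)serialization


def cfa_spec(
    loadings: dict,
    n_items: int | None = None,
    var_names: list | None = None,
    mean_structure: bool = True,
    identification: str = "marker_variable",
    correlated_factors: bool = True,
) -> ModelSpec:
    """Build a CFA ModelSpec from a factor -> items mapping.

    Parameters
    ----------
    loadings : dict
        Maps each factor name to a list of items; each item is either a
        variable name/index (free loading) or a ``(item, value)`` pair for a
        fixed loading.  Under marker-variable identification the first free
        item of each factor is fixed to 1 unless the factor already has a
        fixed loading.
    """
    factor_names = list(loadings)
    q = len(factor_names)
    if var_names is None:
        if n_items is None:
            seen = []
            for items in loadings.values():
                for it in items:
                    name = it[0] if isinstance(it, (tuple, list)) else it
                    if name not in seen:
                        seen.append(name)
            var_names = [str(s) for s in seen]
        else:
            var_names = [f"y{i + 1}" for i in range(n_items)]
    p = len(var_names)
    index = {name: i for i, name in enumerate(var_names)}

    lam_val = np.zeros((p, q))
    lam_free = np.zeros((p, q), dtype=bool)
    for j, fac in enumerate(factor_names):
        fixed_seen = False
        entries = []
        for it in loadings[fac]:
            if isinstance(it, (tuple, list)):
                name, value = it
                entries.append((index[str(name)], float(value), False))
                fixed_seen = True
            else:
                entries.append((index[str(it)], 1.0, True))
        if identification == "marker_variable" and not fixed_seen:
            i0, v0, _ = entries[0]
            entries[0] = (i0, 1.0, False)
        for i, value, free in entries:
            lam_val[i, j] = value
            lam_free[i, j] = free

    psi_val = np.eye(q)
    psi_free = np.zeros((q, q), dtype=bool)
    if identification == "unit_factor_variance":
        psi_free[:] = correlated_factors
        np.fill_diagonal(psi_free, False)
    else:
        psi_free[:] = correlated_factors
        np.fill_diagonal(psi_free, True)
    if not correlated_factors:
        np.fill_diagonal(psi_free, identification != "unit_factor_variance")

    theta_val = np.eye(p) * 0.5
    theta_free = np.zeros((p, p), dtype=bool)
    np.fill_diagonal(theta_free, True)

    return ModelSpec(
        p=p,
        q=q,
        loading=Pattern(lam_val, lam_free),
        structural=Pattern.fixed(np.zeros((q, q))),
        psi=Pattern(psi_val, psi_free),
        theta=Pattern(theta_val, theta_free),
        mean_structure=mean_structure,
        identification=identification,
        var_names=var_names,
        factor_names=factor_names,
    )


def model_spec_to_dict(spec: ModelSpec) -> dict:
    """Serialize a ModelSpec to the structured config dialect."""

    def pat(p: Pattern):
        return {"values": p.values.tolist(), "free": p.free.astype(int).tolist()}

    d = {
        "observed": list(spec.var_names),
        "factors": list(spec.factor_names),
        "loadings": pat(spec.loading),
        "structural": pat(spec.structural),
        "covariances": {"psi": pat(spec.psi), "theta": pat(spec.theta)},
        "means": {"enabled": bool(spec.mean_structure)},
        "identification": spec.identification,
    }
    if spec.mean_structure:
        d["means"]["nu"] = pat(spec.nu)
        d["means"]["alpha"] = pat(spec.alpha)
    return d


def model_spec_from_dict(d: dict) -> ModelSpec:
    def pat(entry) -> Pattern:
        return Pattern(np.asarray(entry["values"], float),
                       np.asarray(entry["free"], bool))

    var_names = [str(v) for v in d["observed"]]
    factor_names = [str(f) for f in d["factors"]]
    means = d.get("means", {"enabled": True})
    mean_structure = bool(means.get("enabled", True))
    return ModelSpec(
        p=len(var_names),
        q=len(factor_names),
        loading=pat(d["loadings"]),
        structural=pat(d["structural"]),
        psi=pat(d["covariances"]["psi"]),
        theta=pat(d["covariances"]["theta"]),
        mean_structure=mean_structure,
        nu=pat(means["nu"]) if mean_structure and "nu" in means else None,
        alpha=pat(means["alpha"]) if mean_structure and "alpha" in means else None,
        identification=d.get("identification", "marker_variable"),
        var_names=var_names,
        factor_names=factor_names,
    )


def save_model_spec(spec: ModelSpec, path) -> None:
    d = model_spec_to_dict(spec)
    text = (
        json.dumps(d, indent=2)
        if str(path).endswith(".json")
        else yaml.safe_dump(d, sort_keys=False)
    )
    with open(path, "w") as fh:
        fh.write(text)


def load_model_spec(path) -> ModelSpec:
    with open(path) as fh:
        text = fh.read()
    d = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    return model_spec_from_dict(d)


# ---------------------------------------------------------------------------
# Unconstrained parameterization used by the optimizers


class Parameterization:
    """Bijection between free model parameters and an unconstrained vector.

    Transform conventions: free diagonal entries of Theta (and of an
    elementwise-parameterized Psi) are optimized as log-variances; a fully
    free Psi is parameterized through its Cholesky factor with log diagonal
    (guaranteeing positive definiteness); all other free entries enter
    identically.  The vector order is nu, Lambda, alpha, B, Psi, Theta.
    """

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        q = spec.q
        self.nu_idx = (
            np.flatnonzero(spec.nu.free) if spec.mean_structure else np.array([], int)
        )
        self.alpha_idx = (
            np.flatnonzero(spec.alpha.free)
            if spec.mean_structure
            else np.array([], int)
        )
        self.lam_idx = np.argwhere(spec.loading.free)
        self.b_idx = np.argwhere(spec.structural.free)
        tril = np.tril_indices(q)
        self.psi_chol = bool(spec.psi.free[tril].all())
        if self.psi_chol:
            self.psi_idx = np.column_stack(tril)
        else:
            self.psi_idx = np.argwhere(np.tril(spec.psi.free))
        self.theta_idx = np.argwhere(np.tril(spec.theta.free))
        self.n_free = (
            len(self.nu_idx)
            + len(self.lam_idx)
            + len(self.alpha_idx)
            + len(self.b_idx)
            + len(self.psi_idx)
            + len(self.theta_idx)
        )
        self._slices()

    def _slices(self):
        start = 0
        self.sl = {}
        for name, idx in [
            ("nu", self.nu_idx),
            ("Lambda", self.lam_idx),
            ("alpha", self.alpha_idx),
            ("B", self.b_idx),
            ("Psi", self.psi_idx),
            ("Theta", self.theta_idx),
        ]:
            self.sl[name] = slice(start, start + len(idx))
            start += len(idx)

    # -- packing -----------------------------------------------------------

    def start_vector(self) -> np.ndarray:
        return self.pack(self.spec.start_parameters())

    def pack(self, params: ParameterSet) -> np.ndarray:
        x = np.empty(self.n_free)
        x[self.sl["nu"]] = params.nu[self.nu_idx]
        x[self.sl["Lambda"]] = params.Lambda[tuple(self.lam_idx.T)] if len(
            self.lam_idx
        ) else []
        x[self.sl["alpha"]] = params.alpha[self.alpha_idx]
        x[self.sl["B"]] = params.B[tuple(self.b_idx.T)] if len(self.b_idx) else []
        if self.psi_chol:
            L = np.linalg.cholesky(params.Psi)
            vals = L[tuple(self.psi_idx.T)]
            diag = self.psi_idx[:, 0] == self.psi_idx[:, 1]
            vals = vals.copy()
            vals[diag] = np.log(vals[diag])
            x[self.sl["Psi"]] = vals
        else:
            vals = params.Psi[tuple(self.psi_idx.T)] if len(self.psi_idx) else np.array([])
            diag = self.psi_idx[:, 0] == self.psi_idx[:, 1] if len(self.psi_idx) else np.array([], bool)
            vals = vals.copy()
            if vals.size:
                vals[diag] = np.log(vals[diag])
            x[self.sl["Psi"]] = vals
        if len(self.theta_idx):
            vals = params.Theta[tuple(self.theta_idx.T)].copy()
            diag = self.theta_idx[:, 0] == self.theta_idx[:, 1]
            vals[diag] = np.log(np.maximum(vals[diag], 1e-12))
            x[self.sl["Theta"]] = vals
        return x

    # -- unpacking ---------------------------------------------------------

    def unpack(self, x: np.ndarray, df: float = np.inf) -> ParameterSet:
        spec = self.spec
        base = spec.start_parameters()
        nu = base.nu
        alpha = base.alpha
        if spec.mean_structure:
            nu[self.nu_idx] = x[self.sl["nu"]]
            alpha[self.alpha_idx] = x[self.sl["alpha"]]
        Lam = base.Lambda
        if len(self.lam_idx):
            Lam[tuple(self.lam_idx.T)] = x[self.sl["Lambda"]]
        B = base.B
        if len(self.b_idx):
            B[tuple(self.b_idx.T)] = x[self.sl["B"]]
        if self.psi_chol:
            L = self._psi_chol_factor(x)
            Psi = L @ L.T
        else:
            Psi = base.Psi
            vals = x[self.sl["Psi"]].copy()
            if vals.size:
                diag = self.psi_idx[:, 0] == self.psi_idx[:, 1]
                vals[diag] = np.exp(vals[diag])
                Psi[tuple(self.psi_idx.T)] = vals
                Psi[tuple(self.psi_idx[:, ::-1].T)] = vals
        Theta = base.Theta
        if len(self.theta_idx):
            vals = x[self.sl["Theta"]].copy()
            diag = self.theta_idx[:, 0] == self.theta_idx[:, 1]
            vals[diag] = np.exp(vals[diag])
            Theta[tuple(self.theta_idx.T)] = vals
            Theta[tuple(self.theta_idx[:, ::-1].T)] = vals
        return ParameterSet(
            nu=nu, Lambda=Lam, alpha=alpha, B=B, Psi=Psi, Theta=Theta, df=df
        )

    def _psi_chol_factor(self, x: np.ndarray) -> np.ndarray:
        q = self.spec.q
        L = np.zeros((q, q))
        vals = x[self.sl["Psi"]].copy()
        diag = self.psi_idx[:, 0] == self.psi_idx[:, 1]
        vals[diag] = np.exp(vals[diag])
        L[tuple(self.psi_idx.T)] = vals
        return L

    # -- gradient chain rule ----------------------------------------------

    def grad_to_vector(
        self, x: np.ndarray, dnu, dLambda, dalpha, dB, dPsi, dTheta
    ) -> np.ndarray:
        """Map natural-scale matrix derivatives to the unconstrained vector.

        ``dPsi`` and ``dTheta`` are full symmetric derivative matrices in the
        trace sense d f = tr(dPsi^T dPsi_matrix): the chain rule applied here
        accounts for symmetry (off-diagonal doubling) and the log/Cholesky
        transforms.
        """
        g = np.empty(self.n_free)
        g[self.sl["nu"]] = dnu[self.nu_idx]
        g[self.sl["alpha"]] = dalpha[self.alpha_idx]
        if len(self.lam_idx):
            g[self.sl["Lambda"]] = dLambda[tuple(self.lam_idx.T)]
        if len(self.b_idx):
            g[self.sl["B"]] = dB[tuple(self.b_idx.T)]
        if self.psi_chol:
            L = self._psi_chol_factor(x)
            GL = 2.0 * dPsi @ L
            vals = GL[tuple(self.psi_idx.T)]
            diag = self.psi_idx[:, 0] == self.psi_idx[:, 1]
            vals = vals.copy()
            vals[diag] *= L[tuple(self.psi_idx[diag].T)]
            g[self.sl["Psi"]] = vals
        elif len(self.psi_idx):
            params_psi = self.unpack(x).Psi
            ii, jj = self.psi_idx.T
            diag = ii == jj
            vals = np.where(diag, dPsi[ii, jj], 2.0 * dPsi[ii, jj])
            vals = np.where(diag, vals * params_psi[ii, jj], vals)
            g[self.sl["Psi"]] = vals
        if len(self.theta_idx):
            Theta = self.unpack(x).Theta
            ii, jj = self.theta_idx.T
            diag = ii == jj
            vals = np.where(diag, dTheta[ii, jj], 2.0 * dTheta[ii, jj])
            vals = np.where(diag, vals * Theta[ii, jj], vals)
            g[self.sl["Theta"]] = vals
        return g

    def bounds(self) -> list:
        """Box bounds for the optimizer: log-scale entries (variances,
        Cholesky diagonal) kept in [-14, 14] to avoid overflow; linear
        entries unbounded."""
        out = [(None, None)] * self.n_free
        psi_sl = self.sl["Psi"]
        if len(self.psi_idx):
            diag = self.psi_idx[:, 0] == self.psi_idx[:, 1]
            for k, is_diag in enumerate(diag):
                if is_diag:
                    out[psi_sl.start + k] = (-14.0, 14.0)
        th_sl = self.sl["Theta"]
        if len(self.theta_idx):
            diag = self.theta_idx[:, 0] == self.theta_idx[:, 1]
            for k, is_diag in enumerate(diag):
                if is_diag:
                    out[th_sl.start + k] = (-14.0, 14.0)
        return out

    # -- naming / reporting -------------------------------------------------

    def free_names(self) -> list:
        spec = self.spec
        names = []
        for i in self.nu_idx:
            names.append(f"nu[{spec.var_names[i]}]")
        for i, j in self.lam_idx:
            names.append(f"lambda[{spec.var_names[i]},{spec.factor_names[j]}]")
        for i in self.alpha_idx:
            names.append(f"alpha[{spec.factor_names[i]}]")
        for i, j in self.b_idx:
            names.append(f"beta[{spec.factor_names[i]},{spec.factor_names[j]}]")
        for i, j in self.psi_idx:
            names.append(f"psi[{spec.factor_names[i]},{spec.factor_names[j]}]")
        for i, j in self.theta_idx:
            names.append(f"theta[{spec.var_names[i]},{spec.var_names[j]}]")
        return names

    def natural_vector(self, x: np.ndarray) -> np.ndarray:
        """Free parameters on the natural scale, aligned with free_names()."""
        params = self.unpack(x)
        out = np.empty(self.n_free)
        out[self.sl["nu"]] = params.nu[self.nu_idx]
        if len(self.lam_idx):
            out[self.sl["Lambda"]] = params.Lambda[tuple(self.lam_idx.T)]
        out[self.sl["alpha"]] = params.alpha[self.alpha_idx]
        if len(self.b_idx):
            out[self.sl["B"]] = params.B[tuple(self.b_idx.T)]
        if len(self.psi_idx):
            out[self.sl["Psi"]] = params.Psi[tuple(self.psi_idx.T)]
        if len(self.theta_idx):
            out[self.sl["Theta"]] = params.Theta[tuple(self.theta_idx.T)]
        return out
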