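"""Bivariate Cholesky ACE twin model fitted by full-information ML.

Trait variance/covariance is partitioned into additive genetic (A), shared
environment (C) and non-shared environment (E) via lower-triangular path
matrices a, c, e with Σ_A = aaᵀ, Σ_C = ccᵀ, Σ_E = eeᵀ — positive
semi-definite by construction.  The expected 4-variate covariance of a twin
pair (t1_twin1, t2_twin1, t1_twin2, t2_twin2) has within-person blocks
Σ_A + Σ_C + Σ_E and cross-twin blocks Σ_A + Σ_C for MZ pairs or
½Σ_A + Σ_C for DZ pairs (DZ additive coefficient fixed at ½; same-sex and
opposite-sex DZ pairs are pooled).  Means are free per trait, shared across
twin order and zygosity.  Pairs with missing cells contribute the
likelihood of their observed sub-vector (FIML).

For two traits the Cholesky and correlated-factors parameterizations are
likelihood-equivalent; the fit reports both the path matrices and the
correlated-factors quantities (Σ components, r_G, r_C, r_E).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize
from sklearn.base import BaseEstimator

__all__ = [
    "TwinDataset",
    "CholeskyACEFit",
    "CholeskyACE",
    "fit_bivariate_cholesky",
    "standardize",
    "component_correlations",
]

_TRAIT_COLS = ["t1_twin1", "t2_twin1", "t1_twin2", "t2_twin2"]
_LT = [(0, 0), (1, 0), (1, 1)]  # lower-triangular index order of a 2x2 factor


@dataclass
class TwinDataset:
    """Validated MZ/DZ twin-pair table (two traits per twin, nan allowed)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ["zygosity", *_TRAIT_COLS] if c not in self.table.columns]
        if missing:
            raise ValueError(f"twin table missing columns: {missing}")
        zyg = self.table["zygosity"]
        if not zyg.isin(["MZ", "DZ"]).all():
            raise ValueError("zygosity must be 'MZ' or 'DZ'")
        for z in ("MZ", "DZ"):
            vals = self.table.loc[zyg == z, _TRAIT_COLS].to_numpy(float)
            if len(vals) and not (~np.isnan(vals)).any(axis=1).any():
                raise ValueError(f"no observed data in {z} group")

    def arrays(self):
        """(mz_values, dz_values) as (n_pairs, 4) float arrays."""
        out = []
        for z in ("MZ", "DZ"):
            out.append(
                self.table.loc[self.table["zygosity"] == z, _TRAIT_COLS].to_numpy(float)
            )
        return tuple(out)

    @property
    def n_pairs(self) -> tuple:
        zyg = self.table["zygosity"]
        return int((zyg == "MZ").sum()), int((zyg == "DZ").sum())


@dataclass
class CholeskyACEFit:
    """Fitted bivariate Cholesky ACE model."""

    a: np.ndarray
    c: np.ndarray
    e: np.ndarray
    means: np.ndarray
    minus2lnl: float
    n_mz: int
    n_dz: int
    param_cov: np.ndarray | None  # covariance of the free parameter vector
    free_components: str
    converged: bool
    param_vector: np.ndarray = None  # type: ignore[assignment]

    @property
    def sigma_a(self) -> np.ndarray:
        return self.a @ self.a.T

    @property
    def sigma_c(self) -> np.ndarray:
        return self.c @ self.c.T

    @property
    def sigma_e(self) -> np.ndarray:
        return self.e @ self.e.T

    @property
    def phenotypic_cov(self) -> np.ndarray:
        return self.sigma_a + self.sigma_c + self.sigma_e

    def expected_cov(self, zygosity: str) -> np.ndarray:
        w = self.phenotypic_cov
        x = (0.5 if zygosity == "DZ" else 1.0) * self.sigma_a + self.sigma_c
        return np.block([[w, x], [x, w]])


# ---------------------------------------------------------------------------
# likelihood machinery
# ---------------------------------------------------------------------------

_COMPONENT_SETS = {"ACE": ("a", "c", "e"), "AE": ("a", "e"), "CE": ("c", "e"), "E": ("e",)}


def _unpack(params, free):
    mats = {"a": np.zeros((2, 2)), "c": np.zeros((2, 2)), "e": np.zeros((2, 2))}
    i = 0
    for name in free:
        for r, s in _LT:
            mats[name][r, s] = params[i]
            i += 1
    means = params[i : i + 2]
    return mats["a"], mats["c"], mats["e"], means


def _pack(a, c, e, means, free):
    vals = []
    for name, m in (("a", a), ("c", c), ("e", e)):
        if name in free:
            vals.extend(m[r, s] for r, s in _LT)
    vals.extend(means)
    return np.array(vals, dtype=float)


def _pattern_groups(values: np.ndarray):
    """Group pair rows by missingness pattern -> [(obs_idx, rows)]."""
    obs = ~np.isnan(values)
    keep = obs.any(axis=1)
    values, obs = values[keep], obs[keep]
    groups = []
    if values.size == 0:
        return groups
    codes = obs @ (1 << np.arange(4))
    for code in np.unique(codes):
        rows = values[codes == code]
        idx = np.flatnonzero(obs[codes == code][0])
        groups.append((idx, rows[:, idx]))
    return groups


def _nll(params, free, groups_mz, groups_dz):
    """-logL over all pairs (with the 2π constant, so -2*nll is OpenMx-style)."""
    a, c, e, means = _unpack(params, free)
    mu4 = np.array([means[0], means[1], means[0], means[1]])
    total = 0.0
    for zyg, groups in (("MZ", groups_mz), ("DZ", groups_dz)):
        sa, sc, se = a @ a.T, c @ c.T, e @ e.T
        w = sa + sc + se
        x = (0.5 if zyg == "DZ" else 1.0) * sa + sc
        sigma = np.block([[w, x], [x, w]])
        for idx, rows in groups:
            s = sigma[np.ix_(idx, idx)]
            try:
                cf = linalg.cho_factor(s)
            except linalg.LinAlgError:
                return np.inf
            dev = rows - mu4[idx]
            sol = linalg.cho_solve(cf, dev.T)
            quad = (dev.T * sol).sum()
            logdet = 2.0 * np.log(np.diag(cf[0])).sum()
            k = idx.size
            total += 0.5 * (rows.shape[0] * (logdet + k * np.log(2 * np.pi)) + quad)
    return total


def _moment_start(mz: np.ndarray, dz: np.ndarray):
    """DeFries-Fulker-style moment estimates as optimizer start values."""

    def _cov(vals):
        df = pd.DataFrame(vals)
        return df.cov(min_periods=2).to_numpy(), np.nanmean(vals, axis=0)

    cmz, mmz = _cov(mz) if len(mz) else (np.eye(4), np.zeros(4))
    cdz, mdz = _cov(dz) if len(dz) else (np.eye(4), np.zeros(4))
    within = 0.5 * (cmz[:2, :2] + cmz[2:, 2:])
    xmz = 0.5 * (cmz[:2, 2:] + cmz[2:, :2])
    xdz = 0.5 * (cdz[:2, 2:] + cdz[2:, :2])
    sa = 2.0 * (xmz - xdz)
    sc = 2.0 * xdz - xmz
    se = within - xmz
    mats = []
    for m in (sa, sc, se):
        m = 0.5 * (m + m.T)
        vals, vecs = np.linalg.eigh(m)
        m = vecs @ np.diag(np.clip(vals, 1e-3, None)) @ vecs.T
        mats.append(np.linalg.cholesky(m))
    means = np.nanmean(np.vstack([mmz.reshape(2, 2), mdz.reshape(2, 2)]), axis=0)
    return mats[0], mats[1], mats[2], means


def _canonical(m: np.ndarray) -> np.ndarray:
    """Flip factor columns so the diagonal is nonnegative (likelihood-invariant)."""
    out = m.copy()
    for j in range(2):
        if out[j, j] < 0:
            out[:, j] = -out[:, j]
    return out


def _numeric_hessian(f, x, step=1e-4):
    n = x.size
    h = np.empty((n, n))
    steps = step * np.maximum(1.0, np.abs(x))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n)
            ej = np.zeros(n)
            ei[i] = steps[i]
            ej[j] = steps[j]
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            h[i, j] = h[j, i] = (fpp - fpm - fmp + fmm) / (4 * steps[i] * steps[j])
    return h


class CholeskyACE(BaseEstimator):
    """Bivariate twin ACE model via Cholesky paths, FIML, multi-start BFGS.

    Parameters
    ----------
    components : one of "ACE", "AE", "CE", "E" — which variance components
        are free (the rest are fixed at zero), for nested-model comparisons.
    n_restarts : random restarts around the moment-based start (seeded);
        the reported solution is the lowest −2lnL across starts.
    seed : seed for the restart perturbations.

    Attributes (after ``fit``)
    --------------------------
    fit_ : :class:`CholeskyACEFit`
    minus2lnl_, rg_, rc_, re_ and their SEs as convenience views.
    """

    def __init__(self, components: str = "ACE", n_restarts: int = 5, seed: int = 0,
                 compute_se: bool = True):
        self.components = components
        self.n_restarts = n_restarts
        self.seed = seed
        self.compute_se = compute_se

    def fit(self, data, y=None):
        if isinstance(data, pd.DataFrame):
            data = TwinDataset(data)
        mz, dz = data.arrays()
        n_mz, n_dz = data.n_pairs
        if n_mz < 20 or n_dz < 20:
            warnings.warn(f"few pairs (MZ={n_mz}, DZ={n_dz}); fit may be unstable",
                          stacklevel=2)
        free = _COMPONENT_SETS[self.components]
        groups_mz = _pattern_groups(mz)
        groups_dz = _pattern_groups(dz)
        obj = lambda p: _nll(p, free, groups_mz, groups_dz)  # noqa: E731

        a0, c0, e0, mu0 = _moment_start(mz, dz)
        x0 = _pack(a0, c0, e0, mu0, free)
        rng = np.random.default_rng(self.seed)
        best = None
        attempts = []
        for trial in range(self.n_restarts + 1):
            start = x0 if trial == 0 else x0 * (1 + 0.3 * rng.standard_normal(x0.size)) \
                + 0.05 * rng.standard_normal(x0.size)
            res = optimize.minimize(obj, start, method="BFGS",
                                    options={"maxiter": 2000, "gtol": 1e-7})
            attempts.append((res.fun, res.success))
            if np.isfinite(res.fun) and (best is None or res.fun < best.fun - 1e-9):
                best = res
        if best is None or not np.isfinite(best.fun):
            raise RuntimeError(f"twin model did not converge; attempts: {attempts}")
        # polish with Nelder-Mead from the best point (robust near boundaries)
        res = optimize.minimize(obj, best.x, method="Nelder-Mead",
                                options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-10})
        if res.fun < best.fun:
            best = res

        a, c, e, means = _unpack(best.x, free)
        a, c, e = _canonical(a), _canonical(c), _canonical(e)
        x_opt = _pack(a, c, e, means, free)

        param_cov = None
        if self.compute_se:
            h = _numeric_hessian(obj, x_opt)
            try:
                param_cov = linalg.inv(h)
                if (np.diag(param_cov) < 0).any():
                    raise linalg.LinAlgError("negative variance")
            except (linalg.LinAlgError, ValueError):
                warnings.warn("singular Hessian: SEs unavailable", stacklevel=2)
                param_cov = None

        self.fit_ = CholeskyACEFit(
            a=a, c=c, e=e, means=np.asarray(means), minus2lnl=2.0 * best.fun,
            n_mz=n_mz, n_dz=n_dz, param_cov=param_cov,
            free_components=self.components, converged=True, param_vector=x_opt,
        )
        self.minus2lnl_ = self.fit_.minus2lnl
        corr = component_correlations(self.fit_)
        self.rg_, self.se_rg_ = corr["r_G"]
        self.rc_, self.se_rc_ = corr["r_C"]
        self.re_, self.se_re_ = corr["r_E"]
        return self


def fit_bivariate_cholesky(data, **opts) -> CholeskyACEFit:
    """Functional wrapper over :class:`CholeskyACE`."""
    return CholeskyACE(**opts).fit(data).fit_


def fit_from_moments(sigma_mz, sigma_dz, n_mz: int = 1000, n_dz: int = 1000,
                     components: str = "ACE", seed: int = 0) -> CholeskyACEFit:
    """Fit the ACE model to population moment matrices (noise-free input).

    Minimizes the same ML discrepancy with the 4x4 covariance matrices as
    sufficient statistics; when the supplied moments are exactly ACE-
    representable the fitted expected covariances reproduce them.
    """
    sigma_mz = np.asarray(sigma_mz, float)
    sigma_dz = np.asarray(sigma_dz, float)
    free = _COMPONENT_SETS[components]

    def obj(p):
        a, c, e, means = _unpack(p, free)
        total = 0.0
        sa, sc, se = a @ a.T, c @ c.T, e @ e.T
        w = sa + sc + se
        for s_obs, n, coef in ((sigma_mz, n_mz, 1.0), (sigma_dz, n_dz, 0.5)):
            x = coef * sa + sc
            sigma = np.block([[w, x], [x, w]])
            try:
                cf = linalg.cho_factor(sigma)
            except linalg.LinAlgError:
                return np.inf
            logdet = 2.0 * np.log(np.diag(cf[0])).sum()
            tr = np.trace(linalg.cho_solve(cf, s_obs))
            mu4 = np.array([means[0], means[1], means[0], means[1]])
            total += 0.5 * n * (logdet + tr + mu4 @ linalg.cho_solve(cf, mu4))
        return total

    # moment start straight from the inputs
    within = 0.5 * (sigma_mz[:2, :2] + sigma_mz[2:, 2:])
    xmz = 0.5 * (sigma_mz[:2, 2:] + sigma_mz[2:, :2])
    xdz = 0.5 * (sigma_dz[:2, 2:] + sigma_dz[2:, :2])
    mats = []
    for m in (2 * (xmz - xdz), 2 * xdz - xmz, within - xmz):
        m = 0.5 * (m + m.T)
        vals, vecs = np.linalg.eigh(m)
        mats.append(np.linalg.cholesky(vecs @ np.diag(np.clip(vals, 1e-6, None)) @ vecs.T))
    x0 = _pack(mats[0], mats[1], mats[2], np.zeros(2), free)
    res = optimize.minimize(obj, x0, method="BFGS", options={"maxiter": 5000, "gtol": 1e-12})
    res = optimize.minimize(obj, res.x, method="Nelder-Mead",
                            options={"maxiter": 5000, "xatol": 1e-11, "fatol": 1e-13})
    a, c, e, means = _unpack(res.x, free)
    return CholeskyACEFit(
        a=_canonical(a), c=_canonical(c), e=_canonical(e), means=np.asarray(means),
        minus2lnl=2.0 * res.fun, n_mz=n_mz, n_dz=n_dz, param_cov=None,
        free_components=components, converged=res.success, param_vector=res.x,
    )


# ---------------------------------------------------------------------------
# derived quantities
# ---------------------------------------------------------------------------


def _derived_se(fit: CholeskyACEFit, func):
    """Delta-method SE of ``func(param_vector)`` from the parameter covariance."""
    if fit.param_cov is None:
        return np.nan
    x = fit.param_vector
    steps = 1e-5 * np.maximum(1.0, np.abs(x))
    grad = np.empty_like(x)
    for i in range(x.size):
        ei = np.zeros_like(x)
        ei[i] = steps[i]
        grad[i] = (func(x + ei) - func(x - ei)) / (2 * steps[i])
    var = float(grad @ fit.param_cov @ grad)
    return float(np.sqrt(max(var, 0.0)))


def _sigmas_from_params(p, free):
    a, c, e, _ = _unpack(p, free)
    return a @ a.T, c @ c.T, e @ e.T


def standardize(fit: CholeskyACEFit) -> dict:
    """Standardized variance/covariance components, twin-table style.

    Per trait each Σ component is divided by the total fitted variance;
    cross-trait components are scaled by √(Vp₁·Vp₂) so the three
    standardized covariance components sum to the fitted phenotypic
    correlation.  SEs by the delta method.
    """
    free = _COMPONENT_SETS[fit.free_components]

    def values(p):
        sa, sc, se = _sigmas_from_params(p, free)
        vp = np.diag(sa + sc + se)
        scale = np.sqrt(vp[0] * vp[1])
        return {
            "V(G)_tr1": sa[0, 0] / vp[0], "V(G)_tr2": sa[1, 1] / vp[1],
            "C(G)_tr12": sa[0, 1] / scale,
            "V(c)_tr1": sc[0, 0] / vp[0], "V(c)_tr2": sc[1, 1] / vp[1],
            "C(c)_tr12": sc[0, 1] / scale,
            "V(e)_tr1": se[0, 0] / vp[0], "V(e)_tr2": se[1, 1] / vp[1],
            "C(e)_tr12": se[0, 1] / scale,
        }

    out = values(fit.param_vector)
    ses = {}
    for key in out:
        ses["SE_" + key] = _derived_se(fit, lambda p, k=key: values(p)[k])
    out.update(ses)
    return out


def component_correlations(fit: CholeskyACEFit) -> dict:
    """r_G, r_C, r_E: each Σ's off-diagonal over the geometric mean of its
    diagonal; delta-method SEs.  A zero diagonal makes the correlation
    undefined (nan)."""
    free = _COMPONENT_SETS[fit.free_components]

    def corr(p, which):
        sa, sc, se = _sigmas_from_params(p, free)
        s = {"A": sa, "C": sc, "E": se}[which]
        denom = np.sqrt(s[0, 0] * s[1, 1])
        if denom <= 1e-12:
            return np.nan
        return s[0, 1] / denom

    out = {}
    for label, which in (("r_G", "A"), ("r_C", "C"), ("r_E", "E")):
        val = corr(fit.param_vector, which)
        se = _derived_se(fit, lambda p, w=which: corr(p, w)) if np.isfinite(val) else np.nan
        out[label] = (float(val) if np.isfinite(val) else np.nan, se)
    return out
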