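"""Variance-component estimation by REML against a genomic relationship matrix.

The univariate model is ``y = Xb + g + e`` with ``g ~ N(0, A σ²_G)`` for GRM
``A`` and ``e ~ N(0, I σ²_e)``; the bivariate model stacks two traits with a
genetic covariance structure ``[[V(G)₁, C(G)₁₂], [C(G)₁₂, V(G)₂]]`` combined
with ``A`` and an analogous residual structure combined with the identity
(residual covariance only within the same individual).  Both are maximized
by one EM-REML step followed by average-information (AI) updates of the
REML log-likelihood

    logL = -1/2 [ log|V| + log|XᵀV⁻¹X| + yᵀPy ],
    P = V⁻¹ - V⁻¹X(XᵀV⁻¹X)⁻¹XᵀV⁻¹,

with step-halving when a proposed update would decrease logL and bending of
the AI matrix when it is not invertible.  Sampling (co)variances of the
components come from the inverse AI matrix at the optimum; correlations and
heritabilities get delta-method standard errors.

When both traits are observed on the same individuals the likelihood
factorizes over the eigenvalues of the GRM into 2x2 blocks, which makes a
single eigendecomposition per dataset the only O(n³) step; individuals with
only one trait are handled by the general dense stacked model
(full-information REML).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from sklearn.base import BaseEstimator

from .grm import GRM

__all__ = [
    "GREML",
    "BivariateGREML",
    "BivariateComponents",
    "UnivariateComponents",
    "reml_univariate",
    "reml_bivariate",
    "genetic_correlation",
    "env_correlation",
    "ConvergenceError",
]

PARAM_NAMES = ("vg1", "cg12", "vg2", "ve1", "ce12", "ve2")


class ConvergenceError(RuntimeError):
    """REML failed to converge; carries the (theta, logL) iteration trace."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace or []


def _corr_delta(v1: float, c: float, v2: float, cov3: np.ndarray):
    """Correlation of components ``c / sqrt(v1 v2)`` with delta-method SE.

    ``cov3`` is the 3x3 sampling covariance of (v1, c, v2).  This is the
    same expression as the expanded per-term variance formula used to derive
    the residual correlation's SE from REML output (each squared/cross term
    of the gradient), written as a quadratic form so that ``c = 0`` needs no
    special-casing.
    """
    if v1 <= 0 or v2 <= 0:
        return np.nan, np.nan
    r = c / np.sqrt(v1 * v2)
    g = np.array([-r / (2.0 * v1), 1.0 / np.sqrt(v1 * v2), -r / (2.0 * v2)])
    var = float(g @ cov3 @ g)
    return float(r), float(np.sqrt(max(var, 0.0)))


@dataclass
class UnivariateComponents:
    vg: float
    ve: float
    vp: float
    h2: float
    se_vg: float
    se_ve: float
    se_h2: float
    sampling_cov: np.ndarray
    loglik: float
    n: int
    n_iter: int
    converged: bool


@dataclass
class BivariateComponents:
    """Bivariate REML estimates in the layout of a two-trait GCTA report."""

    vg1: float
    vg2: float
    cg12: float
    ve1: float
    ve2: float
    ce12: float
    loglik: float
    n: int
    sampling_cov: np.ndarray  # 6x6, order (vg1, cg12, vg2, ve1, ce12, ve2)
    n_iter: int = 0
    converged: bool = True

    @property
    def vp1(self) -> float:
        return self.vg1 + self.ve1

    @property
    def vp2(self) -> float:
        return self.vg2 + self.ve2

    @property
    def h2_1(self) -> float:
        return self.vg1 / self.vp1

    @property
    def h2_2(self) -> float:
        return self.vg2 / self.vp2

    @property
    def rg(self) -> float:
        return genetic_correlation(self)[0]

    @property
    def re(self) -> float:
        return env_correlation(self)[0]

    @property
    def any_negative(self) -> bool:
        """Unconstrained REML may land on negative variance components."""
        return min(self.vg1, self.vg2, self.ve1, self.ve2) < 0

    def se(self, name: str) -> float:
        idx = dict(zip(PARAM_NAMES, range(6)))
        key = {"vg1": "vg1", "vg2": "vg2", "cg12": "cg12",
               "ve1": "ve1", "ve2": "ve2", "ce12": "ce12"}[name]
        return float(np.sqrt(self.sampling_cov[idx[key], idx[key]]))

    def se_vp(self, trait: int) -> float:
        i, j = (0, 3) if trait == 1 else (2, 5)
        s = self.sampling_cov
        return float(np.sqrt(s[i, i] + s[j, j] + 2 * s[i, j]))

    def se_h2(self, trait: int) -> float:
        i, j = (0, 3) if trait == 1 else (2, 5)
        vg = self.vg1 if trait == 1 else self.vg2
        ve = self.ve1 if trait == 1 else self.ve2
        vp = vg + ve
        g = np.array([ve, -vg]) / vp**2
        s = self.sampling_cov[np.ix_([i, j], [i, j])]
        return float(np.sqrt(max(g @ s @ g, 0.0)))

    def to_dict(self) -> dict:
        rg, se_rg = genetic_correlation(self)
        re_, se_re = env_correlation(self)
        return {
            "V(G)_tr1": self.vg1, "V(G)_tr2": self.vg2, "C(G)_tr12": self.cg12,
            "V(e)_tr1": self.ve1, "V(e)_tr2": self.ve2, "C(e)_tr12": self.ce12,
            "Vp_tr1": self.vp1, "Vp_tr2": self.vp2,
            "V(G)/Vp_tr1": self.h2_1, "V(G)/Vp_tr2": self.h2_2,
            "r_G": rg, "r_E": re_,
            "SE_V(G)_tr1": self.se("vg1"), "SE_V(G)_tr2": self.se("vg2"),
            "SE_C(G)_tr12": self.se("cg12"),
            "SE_V(e)_tr1": self.se("ve1"), "SE_V(e)_tr2": self.se("ve2"),
            "SE_C(e)_tr12": self.se("ce12"),
            "SE_Vp_tr1": self.se_vp(1), "SE_Vp_tr2": self.se_vp(2),
            "SE_V(G)/Vp_tr1": self.se_h2(1), "SE_V(G)/Vp_tr2": self.se_h2(2),
            "SE_r_G": se_rg, "SE_r_E": se_re,
            "logL": self.loglik, "n": self.n,
        }


def genetic_correlation(c: BivariateComponents):
    """r_G = C(G)₁₂ / sqrt(V(G)₁ V(G)₂) with delta-method SE.

    Undefined (nan, flagged by the caller) when a genetic variance is
    nonpositive — no silent clamping.
    """
    cov3 = c.sampling_cov[np.ix_([0, 1, 2], [0, 1, 2])]
    return _corr_delta(c.vg1, c.cg12, c.vg2, cov3)


def env_correlation(c: BivariateComponents):
    """r_E = C(e)₁₂ / sqrt(V(e)₁ V(e)₂) with delta-method SE."""
    cov3 = c.sampling_cov[np.ix_([3, 4, 5], [3, 4, 5])]
    return _corr_delta(c.ve1, c.ce12, c.ve2, cov3)


# ---------------------------------------------------------------------------
# model backends: each evaluates logL and the AI-REML derivative quantities
# at a parameter vector, returning None when V is not positive definite.
# ---------------------------------------------------------------------------


class _EigenUnivariate:
    """Univariate REML in the GRM eigenbasis: V = diag(vg * d + ve)."""

    def __init__(self, d, y, x):
        self.d = d
        self.y = y
        self.x = x
        self.n_records = y.size

    def evaluate(self, theta, derivs=True):
        vg, ve = theta
        v = vg * self.d + ve
        if (v <= 0).any():
            return None
        x, y = self.x, self.y
        xv = x / v[:, None]
        xtvx = x.T @ xv
        try:
            cf = linalg.cho_factor(xtvx)
        except linalg.LinAlgError:
            return None
        viy = y / v
        xtvy = x.T @ viy
        beta = linalg.cho_solve(cf, xtvy)
        py = viy - xv @ beta
        ypy = float(y @ py)
        sign, logdet_x = np.linalg.slogdet(xtvx)
        if sign <= 0:
            return None
        logl = -0.5 * (np.log(v).sum() + logdet_x + ypy)
        out = {"logL": float(logl)}
        if not derivs:
            return out
        hs = (self.d, np.ones_like(self.d))
        tr_pvi, ypvipy, us = [], [], []
        for h in hs:
            m = (x * (h / v**2)[:, None]).T @ x
            tr_pvi.append(float((h / v).sum() - np.trace(linalg.cho_solve(cf, m))))
            u = h * py
            us.append(u)
            ypvipy.append(float(py @ u))

        def papply(t):
            vt = t / v
            return vt - xv @ linalg.cho_solve(cf, x.T @ vt)

        ws = [papply(u) for u in us]
        ai = 0.5 * np.array([[us[i] @ ws[j] for j in range(2)] for i in range(2)])
        out.update(trPVi=np.array(tr_pvi), yPViPy=np.array(ypvipy), AI=(ai + ai.T) / 2)
        return out


class _EigenBivariate:
    """Bivariate REML in the GRM eigenbasis; 2x2 block per eigenvalue.

    Requires both traits observed on the same individuals.  Parameter order
    (vg1, cg12, vg2, ve1, ce12, ve2).
    """

    # symmetric 2x2 basis matrices for (11), (12 sym), (22)
    _E = (np.array([[1.0, 0.0], [0.0, 0.0]]),
          np.array([[0.0, 1.0], [1.0, 0.0]]),
          np.array([[0.0, 0.0], [0.0, 1.0]]))

    def __init__(self, d, Y, x):
        self.d = d          # (n,) GRM eigenvalues
        self.Y = Y          # (n, 2) traits in the eigenbasis
        self.x = x          # (n, p) shared fixed-effect design in the eigenbasis
        self.n_records = Y.size

    def _blocks(self, w, out, p):
        """Accumulate per-record 2x2-weighted design cross-products."""
        x = self.x
        out[:p, :p] += np.einsum("n,ni,nj->ij", w[:, 0, 0], x, x)
        out[:p, p:] += np.einsum("n,ni,nj->ij", w[:, 0, 1], x, x)
        out[p:, :p] += np.einsum("n,ni,nj->ij", w[:, 1, 0], x, x)
        out[p:, p:] += np.einsum("n,ni,nj->ij", w[:, 1, 1], x, x)
        return out

    def evaluate(self, theta, derivs=True):
        vg1, cg, vg2, ve1, ce, ve2 = theta
        sg = np.array([[vg1, cg], [cg, vg2]])
        se = np.array([[ve1, ce], [ce, ve2]])
        k = self.d[:, None, None] * sg + se  # (n, 2, 2)
        det = k[:, 0, 0] * k[:, 1, 1] - k[:, 0, 1] ** 2
        if (det <= 0).any() or (k[:, 0, 0] <= 0).any():
            return None
        kinv = np.empty_like(k)
        kinv[:, 0, 0] = k[:, 1, 1] / det
        kinv[:, 1, 1] = k[:, 0, 0] / det
        kinv[:, 0, 1] = kinv[:, 1, 0] = -k[:, 0, 1] / det

        x, Y = self.x, self.Y
        p = x.shape[1]
        viy = np.einsum("nij,nj->ni", kinv, Y)
        xtvx = self._blocks(kinv, np.zeros((2 * p, 2 * p)), p)
        try:
            cf = linalg.cho_factor(xtvx)
        except linalg.LinAlgError:
            return None
        xtvy = np.concatenate([x.T @ viy[:, 0], x.T @ viy[:, 1]])
        beta = linalg.cho_solve(cf, xtvy)
        xb = np.column_stack([x @ beta[:p], x @ beta[p:]])
        py = viy - np.einsum("nij,nj->ni", kinv, xb)
        ypy = float((Y * py).sum())
        sign, logdet_x = np.linalg.slogdet(xtvx)
        if sign <= 0:
            return None
        logl = -0.5 * (np.log(det).sum() + logdet_x + ypy)
        out = {"logL": float(logl)}
        if not derivs:
            return out

        ones = np.ones_like(self.d)
        hs = (self.d, self.d, self.d, ones, ones, ones)
        eidx = (0, 1, 2, 0, 1, 2)

        def vi_apply(i, t):
            h = hs[i]
            u = np.empty_like(t)
            if eidx[i] == 0:
                u[:, 0] = h * t[:, 0]
                u[:, 1] = 0.0
            elif eidx[i] == 2:
                u[:, 0] = 0.0
                u[:, 1] = h * t[:, 1]
            else:
                u[:, 0] = h * t[:, 1]
                u[:, 1] = h * t[:, 0]
            return u

        def p_apply(t):
            vt = np.einsum("nij,nj->ni", kinv, t)
            b = linalg.cho_solve(cf, np.concatenate([x.T @ vt[:, 0], x.T @ vt[:, 1]]))
            xb2 = np.column_stack([x @ b[:p], x @ b[p:]])
            return vt - np.einsum("nij,nj->ni", kinv, xb2)

        tr_pvi = np.empty(6)
        ypvipy = np.empty(6)
        us = []
        for i in range(6):
            h, ei = hs[i], self._E[eidx[i]]
            # tr(V^-1 Vi)
            if eidx[i] == 0:
                tr_v = float((h * kinv[:, 0, 0]).sum())
            elif eidx[i] == 2:
                tr_v = float((h * kinv[:, 1, 1]).sum())
            else:
                tr_v = 2.0 * float((h * kinv[:, 0, 1]).sum())
            # correction tr(B X'V^-1 Vi V^-1 X), via per-record Kinv Ei Kinv
            c = np.einsum("nab,bc,ncd->nad", kinv, ei, kinv) * h[:, None, None]
            m = self._blocks(c, np.zeros((2 * p, 2 * p)), p)
            tr_pvi[i] = tr_v - float(np.trace(linalg.cho_solve(cf, m)))
            u = vi_apply(i, py)
            us.append(u)
            ypvipy[i] = float((py * u).sum())

        ws = [p_apply(u) for u in us]
        ai = 0.5 * np.array([[float((us[i] * ws[j]).sum()) for j in range(6)] for i in range(6)])
        out.update(trPVi=tr_pvi, yPViPy=ypvipy, AI=(ai + ai.T) / 2)
        return out


class _DenseBivariate:
    """General stacked bivariate REML with explicit V (full-information).

    Used when the two traits are observed on non-identical individual sets;
    O(n³) per iteration, intended for modest n.
    """

    def __init__(self, a, y1, y2, obs1, obs2, x_full):
        i1 = np.flatnonzero(obs1)
        i2 = np.flatnonzero(obs2)
        self.y = np.concatenate([y1[i1], y2[i2]])
        n1, n2 = i1.size, i2.size
        self.n_records = n1 + n2
        a11 = a[np.ix_(i1, i1)]
        a12 = a[np.ix_(i1, i2)]
        a22 = a[np.ix_(i2, i2)]
        same = (i1[:, None] == i2[None, :]).astype(float)
        z11 = np.zeros((n1, n1))
        z12 = np.zeros((n1, n2))
        z22 = np.zeros((n2, n2))
        i11 = np.eye(n1)
        i22 = np.eye(n2)
        self.vis = [
            np.block([[a11, z12], [z12.T, z22]]),
            np.block([[z11, a12], [a12.T, z22]]),
            np.block([[z11, z12], [z12.T, a22]]),
            np.block([[i11, z12], [z12.T, z22]]),
            np.block([[z11, same], [same.T, z22]]),
            np.block([[z11, z12], [z12.T, i22]]),
        ]
        x1 = x_full[i1]
        x2 = x_full[i2]
        p = x_full.shape[1]
        self.x = np.zeros((n1 + n2, 2 * p))
        self.x[:n1, :p] = x1
        self.x[n1:, p:] = x2

    def evaluate(self, theta, derivs=True):
        v = sum(t * vi for t, vi in zip(theta, self.vis))
        try:
            cf = linalg.cho_factor(v)
        except linalg.LinAlgError:
            return None
        x, y = self.x, self.y
        vinv = linalg.cho_solve(cf, np.eye(v.shape[0]))
        vix = vinv @ x
        xtvx = x.T @ vix
        try:
            cfx = linalg.cho_factor(xtvx)
        except linalg.LinAlgError:
            return None
        viy = vinv @ y
        beta = linalg.cho_solve(cfx, x.T @ viy)
        py = viy - vix @ beta
        ypy = float(y @ py)
        logdet_v = 2.0 * np.log(np.diag(cf[0])).sum()
        sign, logdet_x = np.linalg.slogdet(xtvx)
        if sign <= 0:
            return None
        logl = -0.5 * (logdet_v + logdet_x + ypy)
        out = {"logL": float(logl)}
        if not derivs:
            return out
        pmat = vinv - vix @ linalg.cho_solve(cfx, vix.T)
        tr_pvi = np.array([float((pmat * vi).sum()) for vi in self.vis])
        us = [vi @ py for vi in self.vis]
        ypvipy = np.array([float(py @ u) for u in us])
        ws = [pmat @ u for u in us]
        ai = 0.5 * np.array([[float(us[i] @ ws[j]) for j in range(6)] for i in range(6)])
        out.update(trPVi=tr_pvi, yPViPy=ypvipy, AI=(ai + ai.T) / 2)
        return out


# ---------------------------------------------------------------------------
# AI-REML driver
# ---------------------------------------------------------------------------


def _ai_reml(model, theta0, max_iter=100, tol=1e-8, em_first=True):
    theta = np.asarray(theta0, dtype=float).copy()
    ev = model.evaluate(theta)
    shrink = 0
    while ev is None and shrink < 20:
        # invalid start (non-PD V): pull covariances toward zero
        theta = 0.5 * theta + 0.5 * np.where(np.arange(theta.size) % 3 == 1, 0.0, theta)
        if theta.size == 2:
            theta = np.abs(theta) + 1e-6
        ev = model.evaluate(theta)
        shrink += 1
    if ev is None:
        raise ConvergenceError("could not find a valid starting point")
    trace = [(theta.copy(), ev["logL"])]
    n = model.n_records
    last_dl = np.inf
    polishes = 0
    for it in range(max_iter):
        if it == 0 and em_first:
            delta = theta**2 * (ev["yPViPy"] - ev["trPVi"]) / n
        else:
            grad = 0.5 * (ev["yPViPy"] - ev["trPVi"])
            ai = ev["AI"].copy()
            eps = 0.0
            while True:
                try:
                    delta = linalg.cho_solve(linalg.cho_factor(ai), grad)
                    break
                except linalg.LinAlgError:
                    # bend: add a ridge proportional to the trace
                    eps = max(2.0 * eps, 1e-6 * np.trace(ev["AI"]))
                    ai = ev["AI"] + eps * np.eye(ai.shape[0])
        new_theta = theta + delta
        new_ev = model.evaluate(new_theta)
        halv = 0
        while (new_ev is None or new_ev["logL"] < ev["logL"] - 1e-10) and halv < 30:
            delta = 0.5 * delta
            new_theta = theta + delta
            new_ev = model.evaluate(new_theta)
            halv += 1
        if new_ev is None or new_ev["logL"] < ev["logL"] - 1e-10:
            # no valid improving AI step: the optimum sits on (or past) the
            # boundary of the positive-definite region, where Newton-type
            # steps stall.  Continue the climb derivative-free, and resume
            # AI only if the simplex made real progress.
            theta2, ev2 = _nm_polish(model, theta, ev)
            trace.append((theta2.copy(), ev2["logL"]))
            if ev2["logL"] > ev["logL"] + 1e-6 and polishes < 3:
                polishes += 1
                theta, ev = theta2, ev2
                last_dl = np.inf
                continue
            return theta2, ev2, trace
        dlogl = new_ev["logL"] - ev["logL"]
        last_dl = dlogl
        theta, ev = new_theta, new_ev
        trace.append((theta.copy(), ev["logL"]))
        if it >= 1 and abs(dlogl) < tol:
            return theta, ev, trace
    if abs(last_dl) < 1e-4:
        # slow crawl along a near-boundary ridge: finish derivative-free
        theta, ev = _nm_polish(model, theta, ev)
        trace.append((theta.copy(), ev["logL"]))
        return theta, ev, trace
    raise ConvergenceError(f"no convergence in {max_iter} iterations", trace)


def _nm_polish(model, theta, ev):
    """Nelder-Mead ascent of the same REML objective from a stalled point.

    Used only when AI steps can no longer improve (boundary optima); the
    simplex crawls along the positive-definite boundary where Newton steps
    keep overshooting.
    """
    from scipy import optimize

    def f(t):
        e = model.evaluate(t, derivs=False)
        return 1e12 if e is None else -e["logL"]

    x = theta
    for _ in range(3):
        res = optimize.minimize(f, x, method="Nelder-Mead",
                                options={"maxiter": 4000, "xatol": 1e-10, "fatol": 1e-12})
        x = res.x
    if -res.fun > ev["logL"]:
        new_ev = model.evaluate(res.x)
        if new_ev is not None:
            return res.x, new_ev
    return theta, ev


def _ai_sampling_cov(model, theta):
    ev = model.evaluate(theta)
    ai = ev["AI"]
    try:
        return linalg.cho_solve(linalg.cho_factor(ai), np.eye(ai.shape[0]))
    except linalg.LinAlgError:
        ai = ai + 1e-6 * np.trace(ai) * np.eye(ai.shape[0])
        return np.linalg.inv(ai)


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------


def _design(n, covariates, obs):
    x = np.ones((n, 1))
    if covariates is not None:
        c = np.asarray(covariates, dtype=float)
        if c.ndim == 1:
            c = c[:, None]
        x = np.column_stack([x, c])
    x = x[obs]
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("rank-deficient fixed-effect design")
    return x


class GREML(BaseEstimator):
    """Univariate GREML: SNP heritability from a GRM by AI-REML.

    Parameters
    ----------
    max_iter, tol : AI-REML iteration cap and |Δ logL| convergence rule.
    em_first : run one EM-REML step before switching to AI updates.

    Attributes (after ``fit``)
    --------------------------
    components_ : :class:`UnivariateComponents`
    h2_, vg_, ve_, loglik_ : convenience views of the same fit.
    """

    def __init__(self, max_iter: int = 100, tol: float = 1e-8, em_first: bool = True):
        self.max_iter = max_iter
        self.tol = tol
        self.em_first = em_first

    def fit(self, grm: GRM, y, covariates=None):
        y = np.asarray(y, dtype=float)
        obs = ~np.isnan(y)
        n = int(obs.sum())
        if n < 30:
            import warnings

            warnings.warn(f"only {n} observations; REML may be unstable", stacklevel=2)
        a = grm.values[np.ix_(np.flatnonzero(obs), np.flatnonzero(obs))]
        x = _design(y.size, covariates, obs)
        d, u = np.linalg.eigh(a)
        model = _EigenUnivariate(d, u.T @ y[obs], u.T @ x)
        vp = y[obs].var(ddof=1)
        theta, ev, trace = _ai_reml(
            model, [vp / 2, vp / 2], self.max_iter, self.tol, self.em_first
        )
        cov = _ai_sampling_cov(model, theta)
        vg, ve = theta
        vptot = vg + ve
        g = np.array([ve, -vg]) / vptot**2
        self.components_ = UnivariateComponents(
            vg=vg, ve=ve, vp=vptot, h2=vg / vptot,
            se_vg=float(np.sqrt(cov[0, 0])), se_ve=float(np.sqrt(cov[1, 1])),
            se_h2=float(np.sqrt(max(g @ cov @ g, 0.0))),
            sampling_cov=cov, loglik=ev["logL"], n=n,
            n_iter=len(trace) - 1, converged=True,
        )
        self.trace_ = trace
        self.vg_, self.ve_, self.h2_ = vg, ve, vg / vptot
        self.loglik_ = ev["logL"]
        return self


class BivariateGREML(BaseEstimator):
    """Bivariate GREML: genetic/residual (co)variances and r_G, r_E.

    ``fit(grm, Y, covariates=None)`` takes an (n, 2) trait array aligned to
    the GRM rows, nan marking a missing trait value.  Individuals observed
    for only one trait still contribute (full-information stacking); the
    reported ``n`` is the pairwise-complete count.
    """

    def __init__(self, max_iter: int = 100, tol: float = 1e-8, em_first: bool = True):
        self.max_iter = max_iter
        self.tol = tol
        self.em_first = em_first

    def fit(self, grm: GRM, Y, covariates=None):
        Y = np.asarray(Y, dtype=float)
        if Y.ndim != 2 or Y.shape[1] != 2:
            raise ValueError("Y must be (n, 2)")
        y1, y2 = Y[:, 0], Y[:, 1]
        obs1, obs2 = ~np.isnan(y1), ~np.isnan(y2)
        for k, o in (("trait1", obs1), ("trait2", obs2)):
            if o.sum() < 30:
                import warnings

                warnings.warn(f"{k}: only {int(o.sum())} observations", stacklevel=2)
        n_pair = int((obs1 & obs2).sum())

        theta0 = self._start(y1, y2, obs1, obs2)
        if (obs1 == obs2).all():
            idx = np.flatnonzero(obs1)
            a = grm.values[np.ix_(idx, idx)]
            x = _design(Y.shape[0], covariates, obs1)
            d, u = np.linalg.eigh(a)
            model = _EigenBivariate(d, u.T @ Y[idx], u.T @ x)
        else:
            x_full = _design(Y.shape[0], covariates, np.ones(Y.shape[0], bool))
            model = _DenseBivariate(grm.values, y1, y2, obs1, obs2, x_full)

        theta, ev, trace = _ai_reml(model, theta0, self.max_iter, self.tol, self.em_first)
        if self._near_boundary(theta):
            # boundary optima can hide a better mode along the PD-boundary
            # ridge; retry from a few deterministic perturbed starts
            for f1, f2 in ((0.4, 1.4), (1.6, 0.4), (0.7, 0.7), (1.3, 1.3)):
                alt = theta0 * np.array([f1, f2 * f1, f1, f2, f2 * f2, f2])
                try:
                    th_a, ev_a, tr_a = _ai_reml(model, alt, self.max_iter, self.tol,
                                                self.em_first)
                except ConvergenceError:
                    continue
                if ev_a["logL"] > ev["logL"] + 1e-9:
                    theta, ev, trace = th_a, ev_a, tr_a
        cov = _ai_sampling_cov(model, theta)
        vg1, cg, vg2, ve1, ce, ve2 = theta
        self.components_ = BivariateComponents(
            vg1=vg1, vg2=vg2, cg12=cg, ve1=ve1, ve2=ve2, ce12=ce,
            loglik=ev["logL"], n=n_pair, sampling_cov=cov,
            n_iter=len(trace) - 1, converged=True,
        )
        self.trace_ = trace
        self.rg_, self.se_rg_ = genetic_correlation(self.components_)
        self.re_, self.se_re_ = env_correlation(self.components_)
        return self

    @staticmethod
    def _near_boundary(theta) -> bool:
        vg1, cg, vg2, ve1, ce, ve2 = theta
        scale = max(abs(x) for x in theta)
        dets = (vg1 * vg2 - cg**2, ve1 * ve2 - ce**2)
        return (min(vg1, vg2, ve1, ve2) < 1e-3 * scale
                or min(dets) < 1e-3 * scale**2)

    @staticmethod
    def _start(y1, y2, obs1, obs2):
        """Half the phenotypic (co)variance to each component.

        A starting genetic correlation at or beyond ±1 is sanitized to
        ±0.5 before optimization.
        """
        v1 = y1[obs1].var(ddof=1)
        v2 = y2[obs2].var(ddof=1)
        both = obs1 & obs2
        cp = np.cov(y1[both], y2[both])[0, 1] if both.sum() > 2 else 0.0
        half = np.array([v1, cp, v2, v1, cp, v2]) / 2.0
        denom = np.sqrt(half[0] * half[2])
        if denom > 0 and abs(half[1]) >= denom:
            half[1] = half[4] = 0.5 * np.sign(half[1]) * denom
        return half


def reml_univariate(grm: GRM, y, covariates=None, **opts) -> UnivariateComponents:
    return GREML(**opts).fit(grm, y, covariates=covariates).components_


def reml_bivariate(grm: GRM, Y, covariates=None, **opts) -> BivariateComponents:
    return BivariateGREML(**opts).fit(grm, Y, covariates=covariates).components_
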