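"""Ancestry principal components and Tracy-Widom axis selection.

PCA is run on column-standardized dosages of the (relatedness- and
LD-pruned) genotype subset: the eigendecomposition of ``(1/m) W Wᵀ`` over
individuals, which is the same spectrum the GRM would give on that subset.
Leading axes are tested one at a time against the Tracy-Widom beta=1 law
following the Patterson/Price moment-matching recipe, and the axes that are
significant at ``alpha`` (stopping at the first non-significant one) are the
ancestry covariates carried into the mixed-model stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from ._tw_table import tw1_sf
from .genotypes import GenotypeMatrix

__all__ = ["PCResult", "AncestryPCA", "pca_axes", "tracy_widom_select"]


@dataclass
class PCResult:
    """Eigenvalues (descending), per-individual loadings, TW statistics."""

    eigenvalues: np.ndarray
    loadings: np.ndarray  # individuals x k, orthonormal columns
    tw_stats: np.ndarray
    tw_pvalues: np.ndarray
    selected_axes: np.ndarray


def tracy_widom_select(eigenvalues, alpha: float = 0.05):
    """Sequential Tracy-Widom significance test on leading eigenvalues.

    For the l-th eigenvalue the remaining spectrum ``λ_l..λ_end`` (size m')
    supplies the moment estimate of the effective column dimension

        n_hat = (m' + 2) S1² / (m' S2 - S1²),

    the top eigenvalue is normalized as ``l = m' λ_l / S1`` and centred/
    scaled with the Tracy-Widom constants for an n_hat x m' white Wishart;
    the p-value comes from the embedded TW1 table.  Selection keeps leading
    axes with p < alpha and stops at the first non-significant axis.

    Returns ``(tw_stats, pvalues, selected_indices)``.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    if lam.size < 3:
        raise ValueError("need at least 3 eigenvalues")
    if np.any(np.diff(lam) > 1e-9):
        raise ValueError("eigenvalues must be sorted descending")
    stats_out = np.full(lam.size, np.nan)
    pvals = np.full(lam.size, np.nan)
    for l in range(lam.size - 2):
        rest = lam[l:]
        if rest[0] <= 0:
            warnings.warn(f"non-positive eigenvalue at axis {l}; skipping", stacklevel=2)
            break
        rest = rest[rest > 0]
        mp = rest.size
        if mp < 3:
            break
        s1, s2 = rest.sum(), (rest**2).sum()
        denom = mp * s2 - s1 * s1
        if denom <= 0:
            break
        n_hat = (mp + 2) * s1 * s1 / denom
        if n_hat <= 1:
            break
        lstat = mp * rest[0] / s1
        sq_n = np.sqrt(n_hat - 1)
        sq_m = np.sqrt(mp)
        mu = (sq_n + sq_m) ** 2 / n_hat
        sigma = (sq_n + sq_m) / n_hat * (1.0 / sq_n + 1.0 / sq_m) ** (1.0 / 3.0)
        stats_out[l] = (lstat - mu) / sigma
        pvals[l] = tw1_sf(stats_out[l])

    selected = []
    for l in range(lam.size):
        if np.isnan(pvals[l]) or not (pvals[l] < alpha):
            break
        selected.append(l)
    return stats_out, pvals, np.asarray(selected, dtype=int)


class AncestryPCA(BaseEstimator, TransformerMixin):
    """PCA of standardized genotypes with Tracy-Widom axis selection.

    Parameters
    ----------
    n_components : int
        Number of leading axes to retain as loadings.
    alpha : float
        Significance level for the sequential Tracy-Widom test.

    Attributes (after ``fit``)
    --------------------------
    eigenvalues_ : full spectrum, descending.
    loadings_ : (n_individuals, n_components) orthonormal axis loadings,
        sign-fixed so each axis's largest-magnitude loading is positive.
    tw_stats_, tw_pvalues_ : per-axis Tracy-Widom statistics / p-values.
    selected_axes_ : indices of the significant leading axes.
    """

    def __init__(self, n_components: int = 10, alpha: float = 0.05):
        self.n_components = n_components
        self.alpha = alpha

    def fit(self, X, y=None):
        w = X.standardized() if isinstance(X, GenotypeMatrix) else self._standardize(np.asarray(X, float))
        n, m = w.shape
        if self.n_components >= min(n, m):
            raise ValueError("n_components must be < min(n_individuals, n_snps)")
        cov = (w @ w.T) / m
        vals, vecs = np.linalg.eigh(cov)
        order = np.argsort(vals)[::-1]
        vals, vecs = vals[order], vecs[:, order]
        k = self.n_components
        load = vecs[:, :k]
        # deterministic sign: largest-|loading| entry positive
        for j in range(k):
            i = np.argmax(np.abs(load[:, j]))
            if load[i, j] < 0:
                load[:, j] = -load[:, j]
        self.eigenvalues_ = vals
        self.loadings_ = load
        self.tw_stats_, self.tw_pvalues_, self.selected_axes_ = tracy_widom_select(
            np.clip(vals, 0.0, None), alpha=self.alpha
        )
        return self

    def fit_transform(self, X, y=None):
        return self.fit(X).loadings_

    def transform(self, X=None):
        return self.loadings_

    def selected_loadings(self) -> np.ndarray:
        """Loadings of the Tracy-Widom-significant axes only."""
        sel = self.selected_axes_[self.selected_axes_ < self.loadings_.shape[1]]
        return self.loadings_[:, sel]

    @staticmethod
    def _standardize(x: np.ndarray) -> np.ndarray:
        p = np.nanmean(x, axis=0) / 2.0
        denom = np.sqrt(2.0 * p * (1.0 - p))
        poly = denom > 0
        w = np.zeros_like(x)
        w[:, poly] = (x[:, poly] - 2.0 * p[poly]) / denom[poly]
        w[np.isnan(w)] = 0.0
        return w


def pca_axes(genotypes, k: int, alpha: float = 0.05) -> PCResult:
    """Functional wrapper over :class:`AncestryPCA`."""
    est = AncestryPCA(n_components=k, alpha=alpha).fit(genotypes)
    return PCResult(
        eigenvalues=est.eigenvalues_,
        loadings=est.loadings_,
        tw_stats=est.tw_stats_,
        tw_pvalues=est.tw_pvalues_,
        selected_axes=est.selected_axes_,
    )
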