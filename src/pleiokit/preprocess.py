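"""Phenotype preprocessing: outlier exclusion, covariate regression,
van der Waerden normalization, composites, one-per-family selection.

The canonical order, applied per test score before compositing, is

    outliers (±3 SD) → regress on sex/age → quantile-normalize → composite

Anthropometric traits (height/weight) follow the same path but skip the
quantile normalization (``quantile=False`` on the pipeline transformer).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "exclude_outliers",
    "residualize",
    "quantile_normalize",
    "make_composite",
    "select_one_per_family",
    "PhenotypePipeline",
]


def exclude_outliers(values, k: float = 3.0) -> np.ndarray:
    """Inclusion mask: False where ``|value - mean| > k * SD``.

    Mean and SD are taken over non-missing values in a single pass (not
    iterated).  Missing values keep a True mask entry — they are neither
    outliers nor observations, and stay missing downstream.  A zero-variance
    vector keeps everything (with a warning).
    """
    x = np.asarray(values, dtype=float)
    obs = ~np.isnan(x)
    if obs.sum() < 2:
        raise ValueError("need at least 2 non-missing values")
    mu = x[obs].mean()
    sd = x[obs].std(ddof=1)
    if sd == 0:
        warnings.warn("zero variance: no outliers excluded", stacklevel=2)
        return np.ones_like(x, dtype=bool)
    mask = np.ones_like(x, dtype=bool)
    mask[obs] = np.abs(x[obs] - mu) <= k * sd
    return mask


def residualize(values, covariates) -> np.ndarray:
    """Standardized OLS residuals of ``values`` on covariates plus intercept.

    Rows with a missing value or missing covariate come back as nan
    (complete-case regression).  Raises if the design is rank-deficient,
    naming the collinear columns.
    """
    y = np.asarray(values, dtype=float)
    c = np.asarray(covariates, dtype=float)
    if c.ndim == 1:
        c = c[:, None]
    x = np.column_stack([np.ones(len(y)), c])
    obs = ~np.isnan(y) & ~np.isnan(c).any(axis=1)
    n_obs = int(obs.sum())
    if n_obs <= x.shape[1]:
        raise ValueError("not enough observations to fit the covariate model")
    rank = np.linalg.matrix_rank(x[obs])
    if rank < x.shape[1]:
        # identify offending columns by testing each against the preceding ones
        bad = []
        for j in range(1, x.shape[1]):
            if np.linalg.matrix_rank(x[obs][:, : j + 1]) <= np.linalg.matrix_rank(x[obs][:, :j]):
                bad.append(j - 1)
        raise ValueError(f"rank-deficient design; collinear covariate columns: {bad}")
    beta, *_ = np.linalg.lstsq(x[obs], y[obs], rcond=None)
    out = np.full_like(y, np.nan)
    resid = y[obs] - x[obs] @ beta
    sd = resid.std(ddof=x.shape[1])
    out[obs] = resid / sd if sd > 0 else 0.0
    return out


def quantile_normalize(values) -> np.ndarray:
    """van der Waerden scores ``Φ⁻¹(r / (n + 1))``.

    ``r`` is the rank among non-missing values with ties given average
    ranks; ``n`` is the non-missing count.  Missing values propagate.
    """
    x = np.asarray(values, dtype=float)
    obs = ~np.isnan(x)
    n = int(obs.sum())
    if n == 0:
        raise ValueError("all values missing")
    if n == 1:
        out = np.full_like(x, np.nan)
        out[obs] = 0.0
        return out
    ranks = stats.rankdata(x[obs], method="average")
    out = np.full_like(x, np.nan)
    out[obs] = stats.norm.ppf(ranks / (n + 1))
    return out


def make_composite(test_scores, min_complete: int) -> np.ndarray:
    """Unit-weighted mean of the non-missing tests per row.

    Rows with fewer than ``min_complete`` observed tests come back missing —
    the 3-of-4 / 2-of-3 completeness rule.
    """
    x = np.asarray(test_scores, dtype=float)
    if x.ndim != 2:
        raise ValueError("test_scores must be 2-D (individuals x tests)")
    if min_complete > x.shape[1]:
        raise ValueError("min_complete exceeds the number of tests")
    n_obs = (~np.isnan(x)).sum(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-nan rows
        comp = np.nanmean(x, axis=1)
    comp[n_obs < min_complete] = np.nan
    return comp


def select_one_per_family(table: pd.DataFrame, seed: int = 0, family_col: str = "fid") -> pd.DataFrame:
    """Keep one uniformly chosen member of each family (e.g. one twin per pair).

    Deterministic given ``seed``; preserves the original row order.
    """
    if family_col not in table.columns:
        raise ValueError(f"missing family column {family_col!r}")
    rng = np.random.default_rng(seed)
    keep = []
    for _, idx in table.groupby(family_col, sort=True).indices.items():
        keep.append(idx[rng.integers(len(idx))])
    return table.iloc[np.sort(np.asarray(keep))]


class PhenotypePipeline(BaseEstimator, TransformerMixin):
    """Per-test preprocessing as a scikit-learn transformer.

    ``fit_transform(X, covariates=C)`` applies, column by column:
    outlier exclusion at ``k_sd`` SDs, OLS regression on the covariates with
    standardized residuals, then van der Waerden quantile normalization
    (skipped when ``quantile=False``, the height/weight path).

    Attributes
    ----------
    outlier_mask_ : boolean ndarray, same shape as X
        False where a value was excluded as an outlier.
    """

    def __init__(self, k_sd: float = 3.0, quantile: bool = True):
        self.k_sd = k_sd
        self.quantile = quantile

    def fit(self, X, y=None, covariates=None):
        self.fit_transform(X, covariates=covariates)
        return self

    def fit_transform(self, X, y=None, covariates=None):
        x = np.asarray(X, dtype=float)
        single = x.ndim == 1
        if single:
            x = x[:, None]
        out = np.empty_like(x)
        self.outlier_mask_ = np.ones_like(x, dtype=bool)
        for j in range(x.shape[1]):
            col = x[:, j].copy()
            mask = exclude_outliers(col, k=self.k_sd)
            self.outlier_mask_[:, j] = mask
            col[~mask] = np.nan
            if covariates is not None:
                col = residualize(col, covariates)
            elif np.nanstd(col) > 0:
                col = (col - np.nanmean(col)) / np.nanstd(col, ddof=1)
            if self.quantile:
                col = quantile_normalize(col)
            out[:, j] = col
        return out[:, 0] if single else out

    def transform(self, X, covariates=None):
        return self.fit_transform(X, covariates=covariates)
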