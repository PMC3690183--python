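"""Genomic relationship matrix, relatedness pruning, LD pruning.

The GRM entry for individuals j,k is the average over SNPs of
``(x_ij - 2p_i)(x_ik - 2p_i) / (2 p_i (1 - p_i))`` with ``p_i`` the sample
alternate-allele frequency — the standard allele-frequency-standardized
relatedness estimator.  Missing genotypes are handled pairwise-complete by
default (each pair is averaged over the SNPs observed in both), with
mean-imputation available for parity with tools that impute to the
frequency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotypes import GenotypeMatrix

__all__ = ["GRM", "compute_grm", "prune_related", "ld_prune"]


@dataclass
class GRM:
    """Symmetric relatedness matrix with per-pair SNP counts."""

    values: np.ndarray
    n_snps: np.ndarray  # per-pair non-missing SNP counts
    sample_ids: np.ndarray
    family_ids: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("GRM must be square")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("GRM must be symmetric")
        self.n_snps = np.asarray(self.n_snps)
        if self.n_snps.shape != (n, n):
            raise ValueError("n_snps must match the GRM shape")
        self.sample_ids = np.asarray(self.sample_ids)
        if self.sample_ids.shape != (n,):
            raise ValueError("sample_ids must have length n")
        if self.family_ids is None:
            self.family_ids = self.sample_ids.copy()
        self.family_ids = np.asarray(self.family_ids)

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    def subset(self, individuals) -> "GRM":
        idx = np.asarray(individuals)
        return GRM(
            values=self.values[np.ix_(idx, idx)],
            n_snps=self.n_snps[np.ix_(idx, idx)],
            sample_ids=self.sample_ids[idx],
            family_ids=self.family_ids[idx],
        )


def compute_grm(genotypes: GenotypeMatrix, impute_to_mean: bool = False) -> GRM:
    """Build the GRM from additive dosages.

    Monomorphic SNPs are skipped.  With ``impute_to_mean`` missing dosages
    are replaced by ``2p`` (contributing zero to the numerator) but the SNP
    still counts in the denominator for every pair; the default divides each
    pair by its own non-missing SNP count.
    """
    if genotypes.n_individuals < 2:
        raise ValueError("need at least 2 individuals")
    p = genotypes.allele_frequencies()
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("no polymorphic SNPs")
    g = genotypes.subset(snps=np.flatnonzero(poly))

    w = g.standardized(impute_missing=True)  # missing -> 0 contribution
    m = g.n_snps
    num = w @ w.T
    if impute_to_mean or not np.isnan(g.dosages).any():
        counts = np.full((g.n_individuals, g.n_individuals), m, dtype=int)
        values = num / m
    else:
        obs = (~np.isnan(g.dosages)).astype(float)
        counts = (obs @ obs.T).astype(int)
        if (counts == 0).any():
            ii, jj = np.nonzero(counts == 0)
            pairs = [(genotypes.sample_ids[a], genotypes.sample_ids[b]) for a, b in zip(ii, jj) if a < b]
            raise ValueError(f"pairs with no shared non-missing SNPs: {pairs[:5]}")
        values = num / counts
    values = (values + values.T) / 2.0
    return GRM(values=values, n_snps=counts, sample_ids=genotypes.sample_ids,
               family_ids=genotypes.family_ids)


def prune_related(grm: GRM, threshold: float = 0.025) -> np.ndarray:
    """Indices of individuals retained after greedy relatedness pruning.

    Repeatedly drops the individual involved in the most over-threshold
    pairs (ties broken by dropping the higher index) until no retained
    off-diagonal exceeds ``threshold``.  The default cutoff 0.025 is the
    fourth-cousin level used to keep a sample "conventionally unrelated".
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    a = grm.values.copy()
    np.fill_diagonal(a, 0.0)
    over = a > threshold
    keep = np.ones(grm.n_individuals, dtype=bool)
    while True:
        counts = (over & keep[None, :] & keep[:, None]).sum(axis=1)
        counts[~keep] = 0
        worst = counts.max()
        if worst == 0:
            break
        # ties -> highest index among the maximally connected
        drop = np.flatnonzero(counts == worst).max()
        keep[drop] = False
    return np.flatnonzero(keep)


def ld_prune(genotypes: GenotypeMatrix, r2_max: float = 0.2, window: int = 50, step: int = 5) -> np.ndarray:
    """Indices of SNPs retained by sliding-window LD pruning.

    Within each window of ``window`` SNPs (advanced by ``step``), whenever a
    retained pair has squared Pearson dosage correlation above ``r2_max``
    the later-positioned SNP is dropped.  With unlinked simulated SNPs this
    retains essentially everything; duplicated columns collapse to one copy.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    x = genotypes.dosages
    m = x.shape[1]
    order = np.argsort(genotypes.positions, kind="stable")
    keep = np.ones(m, dtype=bool)
    start = 0
    while True:
        win = order[start : start + window]
        live = [s for s in win if keep[s]]
        for i_pos, si in enumerate(live):
            if not keep[si]:
                continue
            for sj in live[i_pos + 1 :]:
                if not keep[sj]:
                    continue
                r2 = _pairwise_r2(x[:, si], x[:, sj])
                if r2 > r2_max:
                    keep[sj] = False
        if start + window >= m:
            break
        start += step
    return np.flatnonzero(keep)


def _pairwise_r2(a: np.ndarray, b: np.ndarray) -> float:
    obs = ~np.isnan(a) & ~np.isnan(b)
    if obs.sum() < 2:
        return 0.0
    aa, bb = a[obs], b[obs]
    sa, sb = aa.std(), bb.std()
    if sa == 0 or sb == 0:
        return 0.0
    r = np.mean((aa - aa.mean()) * (bb - bb.mean())) / (sa * sb)
    return float(r * r)
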