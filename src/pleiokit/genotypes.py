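"""Genotype container used throughout the package.

Genotypes are additive dosages (count of the alternate allele, 0/1/2) for
``n`` individuals at ``m`` biallelic SNPs, with ``numpy.nan`` marking missing
calls.  SNP metadata (identifier, position, alleles) and sample identifiers
travel with the matrix so that writers and the GRM builder can stay aligned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class GenotypeMatrix:
    """Additive dosage matrix with SNP and sample metadata.

    Parameters
    ----------
    dosages : ndarray of shape (n_individuals, n_snps)
        Float array of alternate-allele counts in {0, 1, 2}; ``nan`` = missing.
    snp_ids : ndarray of str
        One identifier per SNP.
    positions : ndarray of int
        Base-pair positions on a single pseudo-chromosome.
    ref, alt : ndarray of str
        Reference / alternate alleles per SNP.
    sample_ids : ndarray of str
        One identifier per individual.
    family_ids : ndarray of str, optional
        Family identifier per individual (defaults to the sample id).
    """

    dosages: np.ndarray
    snp_ids: np.ndarray
    positions: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    sample_ids: np.ndarray
    family_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (individuals x SNPs)")
        n, m = self.dosages.shape
        for name in ("snp_ids", "positions", "ref", "alt"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (m,):
                raise ValueError(f"{name} must have length n_snps={m}")
            setattr(self, name, arr)
        self.sample_ids = np.asarray(self.sample_ids)
        if self.sample_ids.shape != (n,):
            raise ValueError(f"sample_ids must have length n_individuals={n}")
        if self.family_ids is None:
            self.family_ids = self.sample_ids.copy()
        self.family_ids = np.asarray(self.family_ids)
        valid = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("dosages must be in {0, 1, 2} or nan")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def allele_frequencies(self) -> np.ndarray:
        """Sample alternate-allele frequency per SNP, ignoring missing calls."""
        return np.nanmean(self.dosages, axis=0) / 2.0

    def subset(self, individuals=None, snps=None) -> "GenotypeMatrix":
        """Return a new matrix restricted to the given index arrays."""
        ind = np.arange(self.n_individuals) if individuals is None else np.asarray(individuals)
        snp = np.arange(self.n_snps) if snps is None else np.asarray(snps)
        return GenotypeMatrix(
            dosages=self.dosages[np.ix_(ind, snp)],
            snp_ids=self.snp_ids[snp],
            positions=self.positions[snp],
            ref=self.ref[snp],
            alt=self.alt[snp],
            sample_ids=self.sample_ids[ind],
            family_ids=self.family_ids[ind],
        )

    def standardized(self, impute_missing: bool = True) -> np.ndarray:
        """Column-standardized dosages ``(x - 2p) / sqrt(2p(1-p))``.

        Monomorphic SNPs come back as all-zero columns.  Missing entries are
        set to 0 (the column mean) when ``impute_missing`` is true, otherwise
        they stay ``nan``.
        """
        p = self.allele_frequencies()
        denom = np.sqrt(2.0 * p * (1.0 - p))
        poly = denom > 0
        w = np.zeros_like(self.dosages)
        w[:, poly] = (self.dosages[:, poly] - 2.0 * p[poly]) / denom[poly]
        if impute_missing:
            w[np.isnan(w)] = 0.0
        return w
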