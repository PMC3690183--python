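"""Synthetic cohorts with known pleiotropic architecture.

Everything downstream (preprocessing, GRM construction, GREML, twin
modelling) is exercised against data generated here, so the generator states
its world explicitly:

* unlinked biallelic SNPs, ancestral frequencies uniform on a MAF range,
  optional population structure via the Balding–Nichols model;
* two quantitative traits built from a shared set of causal SNPs whose
  effect vectors are drawn from a bivariate normal with covariance
  ``sigma_g / n_causal`` on the standardized-genotype scale, plus bivariate
  normal residuals — exactly the additive model GREML assumes, so GREML is
  unbiased under this generator;
* MZ/DZ twin pairs drawn from the 4-variate normal implied by a bivariate
  ACE model with lower-triangular path matrices (DZ additive coefficient ½).

Default parameter values mirror a twin-registry-derived cohort of ~2,500
unrelated 12-year-olds: h² ≈ 0.36 per trait and a genetic correlation
≈ 0.82, the component scale reported for general cognitive ability versus
language skill in cohorts of this size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

__all__ = [
    "SimConfig",
    "simulate_genotypes",
    "simulate_bivariate_phenotypes",
    "simulate_twins",
    "attach_covariates",
    "inject_missingness",
]


def _mvn_factor(cov: np.ndarray) -> np.ndarray:
    """Factor L with L Lᵀ = cov that tolerates PSD-singular matrices
    (e.g. a zero genetic covariance, or a perfect genetic correlation)."""
    vals, vecs = np.linalg.eigh(np.asarray(cov, float))
    return vecs * np.sqrt(np.clip(vals, 0.0, None))


def _check_psd(m: np.ndarray, name: str) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.shape != (2, 2):
        raise ValueError(f"{name} must be 2x2")
    if not np.allclose(m, m.T):
        raise ValueError(f"{name} must be symmetric")
    if np.linalg.eigvalsh(m).min() < -1e-10:
        raise ValueError(f"{name} must be positive semi-definite")
    return m


@dataclass
class SimConfig:
    """Full description of one simulated cohort.

    The defaults are the cohort the package is calibrated against:
    ``sigma_g``/``sigma_e`` on the 'g'-language component scale
    (h² ≈ 0.36, r_G ≈ 0.82, r_E ≈ 0.52) and ACE path matrices that are the
    Cholesky factors of the 'g'-maths twin components.
    """

    n_individuals: int = 2000
    n_snps: int = 5000
    maf_range: tuple = (0.05, 0.5)
    n_causal: int = 500
    sigma_g: np.ndarray = field(
        default_factory=lambda: np.array([[0.36, 0.29], [0.29, 0.35]])
    )
    sigma_e: np.ndarray = field(
        default_factory=lambda: np.array([[0.63, 0.33], [0.33, 0.65]])
    )
    fst: float = 0.0
    subpop_fractions: tuple = (1.0,)
    n_mz: int = 2000
    n_dz: int = 2000
    ace_paths: tuple = field(
        default_factory=lambda: (
            np.linalg.cholesky([[0.46, 0.36], [0.36, 0.48]]),
            np.linalg.cholesky([[0.21, 0.19], [0.19, 0.20]]),
            np.linalg.cholesky([[0.33, 0.07], [0.07, 0.32]]),
        )
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 2 or self.n_snps < 1:
            raise ValueError("need at least 2 individuals and 1 SNP")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not 0 <= self.n_causal <= self.n_snps:
            raise ValueError("n_causal must be in [0, n_snps]")
        self.sigma_g = _check_psd(self.sigma_g, "sigma_g")
        self.sigma_e = _check_psd(self.sigma_e, "sigma_e")
        vp = np.diag(self.sigma_g + self.sigma_e)
        if (vp <= 0).any():
            raise ValueError("implied phenotypic variances must be positive")
        if self.fst < 0:
            raise ValueError("fst must be >= 0")
        fr = np.asarray(self.subpop_fractions, dtype=float)
        if not np.isclose(fr.sum(), 1.0) or (fr <= 0).any():
            raise ValueError("subpop_fractions must be positive and sum to 1")
        if self.n_mz < 0 or self.n_dz < 0:
            raise ValueError("twin-pair counts must be nonnegative")
        a, c, e = (np.asarray(m, dtype=float) for m in self.ace_paths)
        for name, m in (("a", a), ("c", c), ("e", e)):
            if m.shape != (2, 2) or not np.allclose(m, np.tril(m)):
                raise ValueError(f"ACE path matrix {name} must be 2x2 lower-triangular")
        self.ace_paths = (a, c, e)

    @property
    def true_rg(self) -> float:
        return self.sigma_g[0, 1] / np.sqrt(self.sigma_g[0, 0] * self.sigma_g[1, 1])


def simulate_genotypes(
    n: int,
    m: int,
    maf_range=(0.05, 0.5),
    fst: float = 0.0,
    subpop_fractions=(1.0,),
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> GenotypeMatrix:
    """Draw unlinked biallelic genotypes, optionally with population structure.

    Each SNP gets an ancestral frequency ``p ~ Uniform(maf_range)``.  With
    ``fst > 0`` the subpopulation frequencies are Balding–Nichols draws,
    ``Beta(p(1-fst)/fst, (1-p)(1-fst)/fst)``, and dosages are
    ``Binomial(2, p_subpop)``.  With ``fst == 0`` all individuals share the
    ancestral frequency.  Deterministic given ``seed``.
    """
    if n < 2 or m < 1:
        raise ValueError("need n >= 2 individuals and m >= 1 SNPs")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must lie within (0, 0.5]")
    if fst < 0:
        raise ValueError("fst must be >= 0")
    fractions = np.asarray(subpop_fractions, dtype=float)
    if not np.isclose(fractions.sum(), 1.0) or (fractions <= 0).any():
        raise ValueError("subpop_fractions must be positive and sum to 1")
    rng = np.random.default_rng(seed) if rng is None else rng

    k = len(fractions)
    # deterministic assignment of individuals to subpopulations by fractions
    counts = np.floor(fractions * n).astype(int)
    counts[: n - counts.sum()] += 1
    labels = np.repeat(np.arange(k), counts)

    p_anc = rng.uniform(lo, hi, size=m)
    if fst > 0 and k > 1:
        shape1 = p_anc * (1.0 - fst) / fst
        shape2 = (1.0 - p_anc) * (1.0 - fst) / fst
        p_sub = rng.beta(shape1, shape2, size=(k, m))
    else:
        p_sub = np.broadcast_to(p_anc, (k, m))
    dosages = rng.binomial(2, p_sub[labels, :]).astype(float)

    return GenotypeMatrix(
        dosages=dosages,
        snp_ids=np.array([f"snp{i + 1}" for i in range(m)]),
        positions=np.arange(1, m + 1),
        ref=np.full(m, "A"),
        alt=np.full(m, "G"),
        sample_ids=np.array([f"ind{i + 1}" for i in range(n)]),
    )


def simulate_bivariate_phenotypes(
    genotypes: GenotypeMatrix,
    n_causal: int,
    sigma_g,
    sigma_e,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Two additive traits from a shared causal-SNP set.

    Causal SNPs are chosen uniformly without replacement among polymorphic
    SNPs (monomorphic columns carry no variance and are never causal).
    Per-SNP effect vectors are ``MVN(0, sigma_g / n_causal)`` applied to
    standardized dosages, residuals ``MVN(0, sigma_e)``; the population
    phenotypic covariance is therefore ``sigma_g + sigma_e``.

    Returns a frame with columns ``fid, iid, trait1, trait2, g1, g2`` where
    g1/g2 are the true genetic values (handy for oracle checks).
    """
    sigma_g = _check_psd(sigma_g, "sigma_g")
    sigma_e = _check_psd(sigma_e, "sigma_e")
    rng = np.random.default_rng(seed) if rng is None else rng
    n, m = genotypes.dosages.shape
    if n_causal > m:
        raise ValueError("n_causal exceeds the number of SNPs")

    p = genotypes.allele_frequencies()
    poly = np.flatnonzero((p > 0) & (p < 1))
    if n_causal > poly.size:
        raise ValueError("not enough polymorphic SNPs to place causal effects")
    causal = rng.choice(poly, size=n_causal, replace=False) if n_causal else np.array([], int)

    g = np.zeros((n, 2))
    if n_causal:
        w = genotypes.standardized()[:, causal]
        beta = rng.standard_normal((n_causal, 2)) @ _mvn_factor(sigma_g / n_causal).T
        g = w @ beta
    resid = rng.standard_normal((n, 2)) @ _mvn_factor(sigma_e).T
    y = g + resid
    return pd.DataFrame(
        {
            "fid": genotypes.family_ids,
            "iid": genotypes.sample_ids,
            "trait1": y[:, 0],
            "trait2": y[:, 1],
            "g1": g[:, 0],
            "g2": g[:, 1],
        }
    )


def _twin_sigma(a, c, e, dz: bool) -> np.ndarray:
    """Expected 4x4 covariance for (t1_twin1, t2_twin1, t1_twin2, t2_twin2)."""
    sa, sc, se = a @ a.T, c @ c.T, e @ e.T
    within = sa + sc + se
    cross = (0.5 * sa if dz else sa) + sc
    return np.block([[within, cross], [cross, within]])


def simulate_twins(
    n_mz: int,
    n_dz: int,
    a,
    c,
    e,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """MZ/DZ twin pairs from a bivariate ACE model.

    Each pair is one draw from a 4-variate normal with within-person
    covariance ``aaᵀ + ccᵀ + eeᵀ`` and cross-twin covariance ``aaᵀ + ccᵀ``
    (MZ) or ``½aaᵀ + ccᵀ`` (DZ).  Column layout matches the twin TSV writer:
    ``pair_id, zygosity, t1_twin1, t2_twin1, t1_twin2, t2_twin2``.
    """
    if n_mz < 0 or n_dz < 0:
        raise ValueError("pair counts must be nonnegative")
    a, c, e = (np.asarray(m, dtype=float) for m in (a, c, e))
    for name, m in (("a", a), ("c", c), ("e", e)):
        if m.shape != (2, 2) or not np.allclose(m, np.tril(m)):
            raise ValueError(f"path matrix {name} must be 2x2 lower-triangular")
    rng = np.random.default_rng(seed) if rng is None else rng

    rows = []
    for zyg, npairs in (("MZ", n_mz), ("DZ", n_dz)):
        if npairs == 0:
            continue
        sigma = _twin_sigma(a, c, e, dz=(zyg == "DZ"))
        # svd factorisation tolerates the PSD-but-singular case (e.g. c=e=0)
        vals = rng.multivariate_normal(np.zeros(4), sigma, size=npairs, method="svd")
        for i in range(npairs):
            rows.append((f"{zyg.lower()}{i + 1}", zyg, *vals[i]))
    return pd.DataFrame(
        rows, columns=["pair_id", "zygosity", "t1_twin1", "t2_twin1", "t1_twin2", "t2_twin2"]
    )


def attach_covariates(
    phenotypes: pd.DataFrame,
    sex_slopes=(0.0, 0.0),
    age_slopes=(0.0, 0.0),
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Add sex/age covariates and shift the traits linearly by them.

    sex ~ Bernoulli(0.5) coded 0/1, age ~ Uniform(11, 12) years (the cohort
    is measured at age ~11.5).  The planted slopes are recoverable by OLS,
    which is what the preprocessing regression step is tested against.
    """
    out = phenotypes.copy()
    rng = np.random.default_rng(seed) if rng is None else rng
    n = len(out)
    sex = rng.integers(0, 2, size=n).astype(float)
    age = rng.uniform(11.0, 12.0, size=n)
    out["sex"] = sex
    out["age"] = age
    for j, trait in enumerate(("trait1", "trait2")):
        out[trait] = out[trait] + sex_slopes[j] * sex + age_slopes[j] * age
    return out


def inject_missingness(
    values: np.ndarray, rate: float, seed: int = 0, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Set a random ``rate`` fraction of entries to nan (missing at random)."""
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must be in [0, 1)")
    rng = np.random.default_rng(seed) if rng is None else rng
    out = np.asarray(values, dtype=float).copy()
    mask = rng.random(out.shape) < rate
    out[mask] = np.nan
    return out
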