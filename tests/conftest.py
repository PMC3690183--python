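"""Shared fixtures: small simulated cohorts and well-posed toy REML instances."""

import numpy as np
import pytest

from pleiokit.grm import GRM


def pedigree_grm(n: int = 30) -> GRM:
    """Family-structured relatedness: sib pairs at 0.5 and 0.25 plus
    singletons.  Well-conditioned and information-rich at tiny n, so the
    REML surface has an interior optimum with high probability (unlike a
    GRM built from a handful of SNPs)."""
    a = np.eye(n)
    i, k = 0, 0
    rels = (0.5, 0.25)
    while i + 1 < n * 2 // 3:
        a[i, i + 1] = a[i + 1, i] = rels[k % 2]
        k += 1
        i += 2
    return GRM(values=a, n_snps=np.full((n, n), 1000),
               sample_ids=np.array([f"i{j}" for j in range(n)]))


def draw_bivariate(grm: GRM, sigma_g, sigma_e, seed: int) -> np.ndarray:
    """Exact model draw: Y ~ MVN(0, sigma_g ⊗ A + sigma_e ⊗ I), (n, 2)."""
    rng = np.random.default_rng(seed)
    n = grm.n_individuals
    v = np.kron(np.asarray(sigma_g, float), grm.values) + np.kron(
        np.asarray(sigma_e, float), np.eye(n))
    y = rng.multivariate_normal(np.zeros(2 * n), v, method="cholesky")
    return np.column_stack([y[:n], y[n:]])


@pytest.fixture
def toy_grm():
    return pedigree_grm(30)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
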