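"""GRM construction, relatedness pruning, LD pruning, ancestry PCA and the
Tracy-Widom axis test."""

import numpy as np
import pytest

from pleiokit import (
    AncestryPCA,
    GenotypeMatrix,
    compute_grm,
    ld_prune,
    prune_related,
    simulate_genotypes,
    tracy_widom_select,
)
from pleiokit.grm import GRM
from pleiokit._tw_table import tw1_sf


def _geno(dosages, positions=None):
    d = np.asarray(dosages, dtype=float)
    n, m = d.shape
    return GenotypeMatrix(
        dosages=d,
        snp_ids=np.array([f"s{j}" for j in range(m)]),
        positions=np.arange(1, m + 1) if positions is None else np.asarray(positions),
        ref=np.full(m, "A"), alt=np.full(m, "G"),
        sample_ids=np.array([f"i{j}" for j in range(n)]),
    )


class TestComputeGrm:
    def test_hand_worked_single_snp(self):
        # dosages (2, 0), p = 0.5: A_12 = (2-1)(0-1)/(2*0.5*0.5) = -2
        g = _geno([[2], [0]])
        grm = compute_grm(g)
        assert grm.values[0, 1] == pytest.approx(-2.0)
        assert grm.values[0, 0] == pytest.approx(2.0)

    def test_duplicate_individuals_equal_entries(self):
        rng = np.random.default_rng(1)
        row = rng.integers(0, 3, 40).astype(float)
        other = rng.integers(0, 3, 40).astype(float)
        grm = compute_grm(_geno([row, row, other]))
        assert grm.values[0, 1] == pytest.approx(grm.values[0, 0])
        assert grm.values[0, 1] == pytest.approx(grm.values[1, 1])

    def test_matches_wwt_identity_without_missingness(self):
        g = simulate_genotypes(60, 300, seed=2)
        grm = compute_grm(g)
        w = g.standardized()
        m = (g.allele_frequencies() * (1 - g.allele_frequencies()) > 0).sum()
        assert np.abs(grm.values - w @ w.T / m).max() < 1e-10

    def test_mean_off_diagonal_structure(self):
        # sample-frequency centering makes every standardized SNP column sum
        # to zero, so the GRM's entries sum to zero exactly: the mean
        # off-diagonal equals -trace/(n(n-1)) ~ -1/(n-1), not 0
        n, m = 200, 2000
        g = simulate_genotypes(n, m, seed=3)
        grm = compute_grm(g)
        off = grm.values[np.triu_indices(n, 1)]
        trace = grm.values.trace()
        assert off.sum() * 2 == pytest.approx(-trace, abs=1e-8)
        assert abs(off.mean() + 1.0 / (n - 1)) < 3 * (1 / np.sqrt(m)) / np.sqrt(off.size)
        assert grm.values.diagonal().mean() == pytest.approx(1.0, abs=0.1)

    def test_pairwise_complete_counts(self):
        g = simulate_genotypes(10, 50, seed=4)
        g.dosages[0, :30] = np.nan
        grm = compute_grm(g)
        poly = (g.allele_frequencies() > 0) & (g.allele_frequencies() < 1)
        missing_poly = poly[:30].sum()
        assert grm.n_snps[0, 1] == poly.sum() - missing_poly
        assert grm.n_snps[2, 3] == poly.sum()

    def test_monomorphic_only_raises(self):
        with pytest.raises(ValueError, match="polymorphic"):
            compute_grm(_geno([[2], [2], [2]]))

    def test_no_shared_snps_raises(self):
        g = _geno([[2, np.nan], [np.nan, 0], [1, 1]])
        with pytest.raises(ValueError, match="no shared"):
            compute_grm(g)


class TestPruneRelated:
    def _grm(self, values):
        v = np.asarray(values, dtype=float)
        return GRM(values=v, n_snps=np.full(v.shape, 100),
                   sample_ids=np.array([f"i{j}" for j in range(v.shape[0])]))

    def test_unrelated_sample_untouched(self):
        v = np.eye(5) + 0.01
        np.fill_diagonal(v, 1.0)
        assert prune_related(self._grm(v)).size == 5

    def test_single_related_pair_drops_one(self):
        v = np.eye(4) * 1.0
        v[0, 1] = v[1, 0] = 0.5
        kept = prune_related(self._grm(v))
        assert kept.size == 3
        assert 0 in kept and 1 not in kept  # tie broken to the higher index

    def test_star_pattern_removes_hub_only(self):
        # individual 0 related to 1..5; greedy drops the hub, matching the
        # minimum vertex cover of the star graph
        n = 6
        v = np.eye(n)
        for j in range(1, n):
            v[0, j] = v[j, 0] = 0.3
        kept = prune_related(self._grm(v))
        assert 0 not in kept and kept.size == n - 1

    def test_exhaustive_threshold_check(self):
        rng = np.random.default_rng(5)
        v = rng.uniform(-0.02, 0.06, (30, 30))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 1.0)
        g = self._grm(v)
        kept = prune_related(g, threshold=0.025)
        sub = v[np.ix_(kept, kept)]
        np.fill_diagonal(sub, 0.0)
        assert (sub <= 0.025).all()

    def test_bad_threshold(self):
        with pytest.raises(ValueError):
            prune_related(self._grm(np.eye(3)), threshold=0.0)


class TestLdPrune:
    def test_independent_snps_mostly_retained(self):
        g = simulate_genotypes(500, 100, seed=6)
        kept = ld_prune(g)
        assert kept.size >= 97

    def test_duplicated_snp_collapses(self):
        g = simulate_genotypes(200, 30, seed=7)
        d = np.column_stack([g.dosages, g.dosages[:, 0]])
        g2 = _geno(d)
        kept = ld_prune(g2)
        assert (0 in kept) != (30 in kept)  # exactly one of the copies

    def test_planted_correlated_pair_drops_later(self):
        rng = np.random.default_rng(8)
        a = rng.binomial(2, 0.5, 400).astype(float)
        # flip ~25% of entries: r^2 well above 0.2
        b = a.copy()
        flip = rng.random(400) < 0.15
        b[flip] = rng.binomial(2, 0.5, flip.sum())
        others = rng.binomial(2, 0.4, (400, 10)).astype(float)
        g = _geno(np.column_stack([others[:, :5], a, b, others[:, 5:]]))
        kept = ld_prune(g, r2_max=0.2)
        assert 5 in kept and 6 not in kept


class TestAncestryPCA:
    def test_axis1_separates_subpopulations(self):
        g = simulate_genotypes(300, 2000, fst=0.05, subpop_fractions=(0.5, 0.5), seed=9)
        est = AncestryPCA(n_components=5).fit(g)
        labels = np.r_[np.zeros(150), np.ones(150)]
        r = np.corrcoef(est.loadings_[:, 0], labels)[0, 1]
        assert abs(r) > 0.9
        assert 0 in est.selected_axes_

    def test_no_structure_no_separation(self):
        g = simulate_genotypes(300, 2000, seed=10)
        est = AncestryPCA(n_components=5).fit(g)
        labels = np.r_[np.zeros(150), np.ones(150)]
        r = np.corrcoef(est.loadings_[:, 0], labels)[0, 1]
        assert abs(r) < 0.2
        assert est.selected_axes_.size == 0

    def test_loadings_orthonormal(self):
        g = simulate_genotypes(100, 500, seed=11)
        est = AncestryPCA(n_components=8).fit(g)
        gram = est.loadings_.T @ est.loadings_
        assert np.abs(gram - np.eye(8)).max() < 1e-8
        assert (np.diff(est.eigenvalues_) <= 1e-9).all()

    def test_sign_convention_deterministic(self):
        g = simulate_genotypes(100, 500, seed=12)
        l1 = AncestryPCA(n_components=3).fit(g).loadings_
        l2 = AncestryPCA(n_components=3).fit(g).loadings_
        assert np.array_equal(l1, l2)
        for j in range(3):
            assert l1[np.argmax(np.abs(l1[:, j])), j] > 0

    def test_too_many_components_raises(self):
        g = simulate_genotypes(20, 50, seed=13)
        with pytest.raises(ValueError):
            AncestryPCA(n_components=20).fit(g)


class TestTracyWidom:
    def test_embedded_table_quantiles(self):
        # published TW1 quantiles: P(TW1 > 0.9793) = 0.05, P(TW1 > 2.0234) = 0.01
        assert tw1_sf(0.9793) == pytest.approx(0.05, rel=0.03)
        assert tw1_sf(2.0234) == pytest.approx(0.01, rel=0.05)

    def test_null_wishart_calibration(self):
        # fraction of top-axis tests significant at alpha over pure-noise
        # replicates should be near alpha
        rng = np.random.default_rng(14)
        n, m, reps = 60, 300, 200
        hits = 0
        for _ in range(reps):
            x = rng.standard_normal((n, m))
            x = (x - x.mean(0)) / x.std(0)
            lam = np.sort(np.linalg.eigvalsh(x @ x.T / m))[::-1]
            _, pv, _ = tracy_widom_select(lam[:-1], alpha=0.05)
            hits += pv[0] < 0.05
        frac = hits / reps
        assert 0.01 <= frac <= 0.11

    def test_planted_structure_selected(self):
        g = simulate_genotypes(200, 1000, fst=0.1, subpop_fractions=(0.5, 0.5), seed=15)
        est = AncestryPCA(n_components=5).fit(g)
        assert 0 in est.selected_axes_
        assert est.tw_pvalues_[0] < 0.001

    def test_alpha_zero_selects_nothing(self):
        lam = np.sort(np.random.default_rng(16).uniform(0.5, 2.0, 50))[::-1]
        _, _, sel = tracy_widom_select(lam, alpha=0.0)
        assert sel.size == 0

    def test_requires_three_eigenvalues(self):
        with pytest.raises(ValueError):
            tracy_widom_select([2.0, 1.0])
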