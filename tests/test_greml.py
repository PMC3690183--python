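"""AI-REML estimation: oracle equivalence, invariances, recovery, SEs."""

import warnings

import numpy as np
import pytest
from scipy import linalg, optimize

import pleiokit as pk
from pleiokit.greml import (
    BivariateComponents,
    _EigenBivariate,
    _EigenUnivariate,
    env_correlation,
    genetic_correlation,
)

from conftest import draw_bivariate, pedigree_grm

SG = np.array([[0.5, 0.3], [0.3, 0.5]])
SE_ = np.array([[0.5, 0.2], [0.2, 0.5]])


def _nm_oracle(model, base, seed, n_starts=6):
    """Independent derivative-free maximization of the same REML objective."""

    def f(t):
        e = model.evaluate(t, derivs=False)
        return 1e12 if e is None else -e["logL"]

    rng = np.random.default_rng(seed)
    best = None
    for k in range(n_starts):
        x0 = base if k == 0 else base * np.exp(0.4 * rng.standard_normal(base.size))
        r = optimize.minimize(f, x0, method="Nelder-Mead",
                              options={"maxiter": 4000, "xatol": 1e-9, "fatol": 1e-12})
        if best is None or r.fun < best.fun:
            best = r
    return optimize.minimize(f, best.x, method="Nelder-Mead",
                             options={"maxiter": 4000, "xatol": 1e-10, "fatol": 1e-13})


class TestUnivariate:
    def test_null_heritability_recovery(self):
        g = pk.simulate_genotypes(500, 1000, seed=21)
        grm = pk.compute_grm(g)
        rng = np.random.default_rng(22)
        y = rng.standard_normal(500)
        c = pk.reml_univariate(grm, y)
        assert abs(c.h2) < 2 * c.se_h2 + 1e-9

    def test_h2_recovery(self):
        sg = np.array([[0.36, 0.0], [0.0, 0.36]])
        se = np.array([[0.64, 0.0], [0.0, 0.64]])
        g = pk.simulate_genotypes(1000, 2000, seed=23)
        ph = pk.simulate_bivariate_phenotypes(g, 300, sg, se, seed=24)
        grm = pk.compute_grm(g)
        c = pk.reml_univariate(grm, ph["trait1"].to_numpy())
        assert abs(c.h2 - 0.36) < 2 * c.se_h2

    def test_oracle_equivalence_toy(self):
        # grid/Nelder-Mead maximization of the identical objective agrees to
        # 4 decimals on a well-posed pedigree toy
        grm = pedigree_grm(24)
        y = draw_bivariate(grm, SG, SE_, seed=25)[:, 0]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est = pk.GREML().fit(grm, y)
        d, u = np.linalg.eigh(grm.values)
        model = _EigenUnivariate(d, u.T @ y, u.T @ np.ones((24, 1)))
        vp = y.var(ddof=1)
        r = _nm_oracle(model, np.array([vp / 2, vp / 2]), seed=26)
        assert np.abs(r.x - [est.vg_, est.ve_]).max() < 1e-4

    def test_em_iterations_never_decrease_loglik(self, toy_grm):
        y = draw_bivariate(toy_grm, SG, SE_, seed=27)[:, 0]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est = pk.GREML().fit(toy_grm, y)
        logls = [l for _, l in est.trace_]
        assert all(b >= a - 1e-9 for a, b in zip(logls, logls[1:]))


class TestBivariate:
    def test_duplicated_trait_rg_one(self):
        g = pk.simulate_genotypes(200, 400, seed=28)
        ph = pk.simulate_bivariate_phenotypes(
            g, 100, np.array([[0.4, 0.0], [0.0, 0.4]]), np.array([[0.6, 0.0], [0.0, 0.6]]),
            seed=29)
        y = ph["trait1"].to_numpy()
        est = pk.BivariateGREML().fit(pk.compute_grm(g), np.column_stack([y, y]))
        assert est.rg_ == pytest.approx(1.0, abs=1e-3)

    def test_component_recovery_table2_scale(self):
        # generating components on the 'g'-language scale; estimates within
        # 2 SE of truth (single replicate; the replicated version is the
        # acceptance check)
        sg = np.array([[0.36, 0.29], [0.29, 0.35]])
        se = np.array([[0.63, 0.33], [0.33, 0.65]])
        g = pk.simulate_genotypes(1200, 2500, seed=30)
        ph = pk.simulate_bivariate_phenotypes(g, 400, sg, se, seed=31)
        est = pk.BivariateGREML().fit(pk.compute_grm(g),
                                      ph[["trait1", "trait2"]].to_numpy())
        c = est.components_
        truth = dict(vg1=0.36, cg12=0.29, vg2=0.35, ve1=0.63, ce12=0.33, ve2=0.65)
        for name, t in truth.items():
            assert abs(getattr(c, name) - t) < 2 * c.se(name) + 0.02

    def test_oracle_equivalence_toys(self):
        # a handful here; the 25-instance version is the acceptance check
        for seed in range(5):
            grm = pedigree_grm(30)
            y = draw_bivariate(grm, SG, SE_, seed=40 + seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                est = pk.BivariateGREML().fit(grm, y)
            c = est.components_
            th = np.array([c.vg1, c.cg12, c.vg2, c.ve1, c.ce12, c.ve2])
            d, u = np.linalg.eigh(grm.values)
            model = _EigenBivariate(d, u.T @ y, u.T @ np.ones((30, 1)))
            base = pk.BivariateGREML._start(y[:, 0], y[:, 1],
                                            ~np.isnan(y[:, 0]), ~np.isnan(y[:, 1]))
            r = _nm_oracle(model, base, seed=50 + seed)
            assert np.abs(r.x - th).max() < 1e-3

    def test_affine_covariate_invariance(self, toy_grm):
        rng = np.random.default_rng(51)
        covar = rng.standard_normal((30, 2))
        y = draw_bivariate(toy_grm, SG, SE_, seed=52)
        y[:, 0] += covar @ [0.3, -0.2]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = pk.BivariateGREML().fit(toy_grm, y, covariates=covar).components_
            b = pk.BivariateGREML().fit(toy_grm, y, covariates=2.0 * covar + 5.0).components_
        for name in ("vg1", "cg12", "vg2", "ve1", "ce12", "ve2"):
            assert getattr(a, name) == pytest.approx(getattr(b, name), abs=1e-6)

    def test_rg_invariant_to_trait_rescaling(self, toy_grm):
        y = draw_bivariate(toy_grm, SG, SE_, seed=53)
        y2 = y.copy()
        y2[:, 1] *= 3.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = pk.BivariateGREML().fit(toy_grm, y)
            b = pk.BivariateGREML().fit(toy_grm, y2)
        assert a.rg_ == pytest.approx(b.rg_, abs=1e-5)

    def test_full_information_missing_traits(self):
        # non-identical individual sets exercise the dense stacked model
        grm = pedigree_grm(60)
        y = draw_bivariate(grm, SG, SE_, seed=54)
        y[:5, 0] = np.nan
        y[-5:, 1] = np.nan
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est = pk.BivariateGREML().fit(grm, y)
        assert est.components_.n == 50  # pairwise-complete count
        assert np.isfinite(est.components_.loglik)
        # against the complete-data fit the estimates should be in the same
        # ballpark (small perturbation of the sample)
        est_full = pk.BivariateGREML().fit(grm, draw_bivariate(grm, SG, SE_, seed=54))
        assert abs(est.components_.vg1 - est_full.components_.vg1) < 1.0

    def test_rank_deficient_design_raises(self, toy_grm):
        y = draw_bivariate(toy_grm, SG, SE_, seed=55)
        bad = np.ones((30, 1))  # duplicates the intercept
        with pytest.raises(ValueError, match="rank-deficient"):
            pk.BivariateGREML().fit(toy_grm, y, covariates=bad)


class TestCorrelations:
    def _components(self, vg1, vg2, cg, ve1, ve2, ce, cov=None):
        return BivariateComponents(
            vg1=vg1, vg2=vg2, cg12=cg, ve1=ve1, ve2=ve2, ce12=ce,
            loglik=0.0, n=100,
            sampling_cov=np.zeros((6, 6)) if cov is None else cov,
        )

    def test_zero_genetic_covariance(self):
        cov = np.zeros((6, 6))
        cov[1, 1] = 0.04  # Var(C(G))
        c = self._components(0.4, 0.5, 0.0, 0.6, 0.5, 0.1, cov)
        rg, se = genetic_correlation(c)
        assert rg == 0.0
        assert se == pytest.approx(np.sqrt(0.04) / np.sqrt(0.4 * 0.5))

    def test_nonpositive_variance_flagged(self):
        c = self._components(-0.1, 0.5, 0.1, 0.6, 0.5, 0.1)
        rg, se = genetic_correlation(c)
        assert np.isnan(rg) and np.isnan(se)

    def test_zero_residual_covariance(self):
        c = self._components(0.4, 0.5, 0.2, 0.6, 0.5, 0.0)
        re_, _ = env_correlation(c)
        assert re_ == 0.0

    def test_delta_se_matches_parametric_bootstrap(self):
        # the delta-method SE of r_E should match the spread of refitted
        # estimates over data re-drawn from the fitted model; the bulk
        # spread (IQR-based) is compared because small-sample unconstrained
        # REML produces occasional boundary blow-ups in the tails
        from scipy import stats as sps

        grm = pedigree_grm(240)
        y = draw_bivariate(grm, SG, SE_, seed=60)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est = pk.BivariateGREML().fit(grm, y)
        c = est.components_
        sg_hat = np.array([[c.vg1, c.cg12], [c.cg12, c.vg2]])
        se_hat = np.array([[c.ve1, c.ce12], [c.ce12, c.ve2]])
        boots = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for b in range(40):
                yb = draw_bivariate(grm, sg_hat, se_hat, seed=600 + b)
                try:
                    eb = pk.BivariateGREML().fit(grm, yb)
                except Exception:
                    continue
                if np.isfinite(eb.re_):
                    boots.append(eb.re_)
        assert len(boots) >= 30
        emp_sd = sps.iqr(boots) / 1.349
        _, se_delta = env_correlation(c)
        assert se_delta == pytest.approx(emp_sd, rel=0.5)

    def test_identity_vp_and_h2(self):
        c = self._components(0.36, 0.35, 0.29, 0.63, 0.65, 0.33)
        assert c.vp1 == pytest.approx(c.vg1 + c.ve1)
        assert c.h2_1 == pytest.approx(0.36 / 0.99)
        d = c.to_dict()
        assert d["r_G"] == pytest.approx(0.29 / np.sqrt(0.36 * 0.35))
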