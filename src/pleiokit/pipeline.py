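"""Config-driven end-to-end runs: simulate (or ingest) → preprocess →
GRM/PCA → one-per-family GREML → twin fit → tabulated reports.

One run analyses one trait pair along two routes that share the same
generating architecture:

* the DNA route — a genotyped cohort laid out as MZ-like families of two
  (co-twins share genetic values), from which one member per family is
  randomly selected, close relatives are pruned from the GRM, ancestry
  axes are screened by the Tracy-Widom test and carried as covariates into
  bivariate GREML;
* the twin route — MZ/DZ pairs drawn from the ACE model implied by the
  same genetic/residual covariance matrices (Σ_A = sigma_g, Σ_C optional,
  Σ_E = sigma_e), fitted with the bivariate Cholesky ACE model.

The emitted reports mirror the shape of the published tables: a summary of
the two genetic-correlation estimates side by side, the full bivariate
GREML component set, and the full twin component set, plus machine-readable
run metadata with every defaulted parameter recorded.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .genotypes import GenotypeMatrix
from .greml import BivariateGREML
from .grm import compute_grm, ld_prune, prune_related
from .pca import AncestryPCA
from .preprocess import PhenotypePipeline, select_one_per_family
from .simulate import SimConfig, simulate_bivariate_phenotypes, simulate_genotypes, simulate_twins
from .twin import CholeskyACE, component_correlations, standardize

__all__ = ["RunConfig", "run_pipeline", "check_table_consistency"]

logger = logging.getLogger("pleiokit")


@dataclass
class RunConfig:
    """Everything one pipeline run needs; every default is recorded in
    ``run.json`` so reruns with an identical config are byte-identical
    (modulo timestamps)."""

    sim: SimConfig = field(default_factory=SimConfig)
    # preprocessing
    outlier_sd: float = 3.0
    quantile_normalize: bool = True
    # GRM / PCA
    ld_r2_max: float = 0.2
    ld_window: int = 50
    ld_step: int = 5
    relatedness_threshold: float = 0.025
    pca_axes: int = 10
    tw_alpha: float = 0.05
    # GREML / twin options
    greml_max_iter: int = 100
    greml_tol: float = 1e-8
    twin_restarts: int = 5
    # C (shared environment) variance injected into the twin route; the DNA
    # route has no C, so 0 keeps both routes on the same ground truth
    twin_c_matrix: np.ndarray | None = None
    pair_label: str = "trait1 vs trait2"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim", {})
        for key in ("sigma_g", "sigma_e"):
            if key in sim_raw:
                sim_raw[key] = np.asarray(sim_raw[key], dtype=float)
        if "ace_paths" in sim_raw:
            sim_raw["ace_paths"] = tuple(np.asarray(m, float) for m in sim_raw["ace_paths"])
        if "maf_range" in sim_raw:
            sim_raw["maf_range"] = tuple(sim_raw["maf_range"])
        if "subpop_fractions" in sim_raw:
            sim_raw["subpop_fractions"] = tuple(sim_raw["subpop_fractions"])
        twin_c = raw.pop("twin_c_matrix", None)
        cfg = cls(sim=SimConfig(**sim_raw),
                  twin_c_matrix=None if twin_c is None else np.asarray(twin_c, float),
                  **raw)
        return cfg

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d["sim"] = {k: (v.tolist() if isinstance(v, np.ndarray)
                        else [m.tolist() for m in v] if k == "ace_paths" else v)
                    for k, v in asdict(self.sim).items()}
        if self.twin_c_matrix is not None:
            d["twin_c_matrix"] = np.asarray(self.twin_c_matrix).tolist()
        return d


def _twin_paths(cfg: RunConfig):
    """ACE path matrices implied by the simulation's covariance matrices."""
    sigma_c = np.zeros((2, 2)) if cfg.twin_c_matrix is None else np.asarray(cfg.twin_c_matrix)

    def chol(m):
        vals, vecs = np.linalg.eigh(m)
        return np.linalg.cholesky(vecs @ np.diag(np.clip(vals, 1e-12, None)) @ vecs.T)

    return chol(cfg.sim.sigma_g), chol(sigma_c), chol(cfg.sim.sigma_e)


def _simulate_family_cohort(cfg: RunConfig, rng):
    """Genotyped cohort of MZ-like families: co-twins share genotypes and
    genetic values, with independent residual deviations."""
    sim = cfg.sim
    g = simulate_genotypes(sim.n_individuals, sim.n_snps, sim.maf_range,
                           sim.fst, sim.subpop_fractions, rng=rng)
    pheno_a = simulate_bivariate_phenotypes(g, sim.n_causal, sim.sigma_g, sim.sigma_e, rng=rng)
    # co-twin: same genetic value, fresh residuals
    from .simulate import _mvn_factor

    resid = rng.standard_normal((sim.n_individuals, 2)) @ _mvn_factor(sim.sigma_e).T
    pheno_b = pheno_a.copy()
    pheno_b["trait1"] = pheno_a["g1"] + resid[:, 0]
    pheno_b["trait2"] = pheno_a["g2"] + resid[:, 1]
    fam = np.array([f"fam{i + 1}" for i in range(sim.n_individuals)])
    for df, tag in ((pheno_a, "a"), (pheno_b, "b")):
        df["fid"] = fam
        df["iid"] = [f"{f}_{tag}" for f in fam]
    cohort = pd.concat([pheno_a, pheno_b], ignore_index=True)

    dup = GenotypeMatrix(
        dosages=np.vstack([g.dosages, g.dosages]),
        snp_ids=g.snp_ids, positions=g.positions, ref=g.ref, alt=g.alt,
        sample_ids=cohort["iid"].to_numpy(), family_ids=cohort["fid"].to_numpy(),
    )
    return dup, cohort


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Run simulate → preprocess → GRM/PCA → GREML and the twin fit; write
    ``table1.tsv``, ``table2.tsv``, ``table3.tsv``, ``run.json`` and a log
    file into ``out_dir``.  Returns the report as a dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    stage = "setup"
    try:
        rng = np.random.default_rng(config.seed)
        report: dict = {"pair": config.pair_label, "seed": config.seed}

        stage = "simulate"
        logger.info("simulating cohort: %s", config.sim)
        geno, cohort = _simulate_family_cohort(config, rng)
        a_paths, c_paths, e_paths = _twin_paths(config)
        twins = simulate_twins(config.sim.n_mz, config.sim.n_dz,
                               a_paths, c_paths, e_paths, rng=rng)

        stage = "preprocess"
        pipe = PhenotypePipeline(k_sd=config.outlier_sd, quantile=config.quantile_normalize)
        traits = pipe.fit_transform(cohort[["trait1", "trait2"]].to_numpy())
        cohort = cohort.assign(trait1=traits[:, 0], trait2=traits[:, 1])
        one = select_one_per_family(cohort, seed=int(rng.integers(2**31)))
        keep_iids = set(one["iid"])
        keep_idx = np.flatnonzero(np.isin(geno.sample_ids, list(keep_iids)))
        geno_one = geno.subset(individuals=keep_idx)
        pheno_one = one.set_index("iid").loc[geno_one.sample_ids]
        logger.info("selected one per family: %d individuals", len(pheno_one))

        stage = "grm"
        grm = compute_grm(geno_one)
        noise_sd = 1.0 / np.sqrt(config.sim.n_snps)
        if config.relatedness_threshold < 3 * noise_sd:
            logger.warning(
                "relatedness threshold %.3f is below 3x the GRM noise SD (%.3f at "
                "%d SNPs); pruning will remove unrelated individuals",
                config.relatedness_threshold, noise_sd, config.sim.n_snps)
        retained = prune_related(grm, threshold=config.relatedness_threshold)
        grm = grm.subset(retained)
        geno_one = geno_one.subset(individuals=retained)
        pheno_one = pheno_one.iloc[retained]
        logger.info("relatedness pruning retained %d individuals", len(retained))

        stage = "pca"
        kept_snps = ld_prune(geno_one, r2_max=config.ld_r2_max,
                             window=config.ld_window, step=config.ld_step)
        pca = AncestryPCA(n_components=config.pca_axes, alpha=config.tw_alpha)
        pca.fit(geno_one.subset(snps=kept_snps))
        covar = pca.selected_loadings()
        covar = covar if covar.size else None
        logger.info("LD pruning kept %d SNPs; %d TW-significant axes",
                    kept_snps.size, 0 if covar is None else covar.shape[1])

        stage = "greml"
        est = BivariateGREML(max_iter=config.greml_max_iter, tol=config.greml_tol)
        est.fit(grm, pheno_one[["trait1", "trait2"]].to_numpy(), covariates=covar)
        comp = est.components_
        report["greml"] = comp.to_dict()
        report["greml"]["negative_component"] = bool(comp.any_negative)
        logger.info("GREML r_G=%.3f (SE %.3f)", est.rg_, est.se_rg_)

        stage = "twin"
        twin_est = CholeskyACE(n_restarts=config.twin_restarts,
                               seed=int(rng.integers(2**31)))
        twin_est.fit(twins)
        tw_std = standardize(twin_est.fit_)
        tw_corr = component_correlations(twin_est.fit_)
        report["twin"] = {
            **tw_std,
            "r_G": tw_corr["r_G"][0], "SE_r_G": tw_corr["r_G"][1],
            "r_C": tw_corr["r_C"][0], "SE_r_C": tw_corr["r_C"][1],
            "r_E": tw_corr["r_E"][0], "SE_r_E": tw_corr["r_E"][1],
            "-2lnL": twin_est.minus2lnl_,
            "n_pairs": twin_est.fit_.n_mz + twin_est.fit_.n_dz,
        }
        logger.info("twin r_G=%.3f (SE %.3f)", twin_est.rg_, twin_est.se_rg_)

        stage = "report"
        _write_tables(report, out)
        meta = {
            "package_version": __version__,
            "config": config.to_jsonable(),
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "stages": ["simulate", "preprocess", "grm", "pca", "greml", "twin", "report"],
        }
        with open(out / "run.json", "w") as fh:
            json.dump({"meta": meta, "report": report}, fh, indent=2, default=float)
        return report
    except Exception:
        logger.exception("pipeline failed in stage %s", stage)
        raise RuntimeError(f"pipeline failed in stage '{stage}' (partial outputs in {out})")
    finally:
        logger.removeHandler(handler)
        handler.close()


def _fmt(v, se=None):
    if se is None or not np.isfinite(se):
        return f"{v:.2f}"
    return f"{v:.2f}({se:.2f})"


def _write_tables(report: dict, out: Path) -> None:
    g = report["greml"]
    t = report["twin"]
    pd.DataFrame([{
        "bivariate_comparison": report["pair"],
        "GCTA_rG(SE)": _fmt(g["r_G"], g["SE_r_G"]),
        "Twin_rG(SE)": _fmt(t["r_G"], t["SE_r_G"]),
    }]).to_csv(out / "table1.tsv", sep="\t", index=False)

    cols2 = ["V(G)_tr1", "V(G)_tr2", "C(G)_tr12", "V(G)/Vp_tr1", "V(G)/Vp_tr2", "r_G",
             "V(e)_tr1", "V(e)_tr2", "C(e)_tr12", "r_E", "Vp_tr1", "Vp_tr2"]
    row2 = {"bivariate_comparison": report["pair"]}
    for c in cols2:
        row2[c] = _fmt(g[c], g.get("SE_" + c))
    row2["logL"] = f"{g['logL']:.2f}"
    row2["n"] = g["n"]
    pd.DataFrame([row2]).to_csv(out / "table2.tsv", sep="\t", index=False)

    cols3 = ["V(G)_tr1", "V(G)_tr2", "C(G)_tr12", "r_G",
             "V(c)_tr1", "V(c)_tr2", "C(c)_tr12", "r_C",
             "V(e)_tr1", "V(e)_tr2", "C(e)_tr12", "r_E"]
    row3 = {"bivariate_comparison": report["pair"]}
    for c in cols3:
        row3[c] = _fmt(t[c], t.get("SE_" + c))
    row3["n_pairs"] = t["n_pairs"]
    pd.DataFrame([row3]).to_csv(out / "table3.tsv", sep="\t", index=False)


def check_table_consistency(report: dict, tol: float = 0.02) -> list:
    """Assert the ratio identities among reported columns.

    Checks, on the GREML side: r_G = C(G)/√(V(G)₁V(G)₂),
    r_E = C(e)/√(V(e)₁V(e)₂), h² = V(G)/Vp and Vp = V(G)+V(e); on the twin
    side: r_X consistency with the standardized components.  Returns a list
    of ``(check_name, passed)`` tuples.
    """
    out = []
    g = report.get("greml")
    if g:
        rg = g["C(G)_tr12"] / np.sqrt(g["V(G)_tr1"] * g["V(G)_tr2"])
        re_ = g["C(e)_tr12"] / np.sqrt(g["V(e)_tr1"] * g["V(e)_tr2"])
        out.append(("greml_rG_identity", abs(rg - g["r_G"]) <= tol))
        out.append(("greml_rE_identity", abs(re_ - g["r_E"]) <= tol))
        for tr in ("tr1", "tr2"):
            h2 = g[f"V(G)_{tr}"] / g[f"Vp_{tr}"]
            out.append((f"greml_h2_identity_{tr}", abs(h2 - g[f"V(G)/Vp_{tr}"]) <= tol))
            vp = g[f"V(G)_{tr}"] + g[f"V(e)_{tr}"]
            out.append((f"greml_vp_identity_{tr}", abs(vp - g[f"Vp_{tr}"]) <= tol))
    t = report.get("twin")
    if t:
        for comp, label in (("G", "r_G"), ("c", "r_C"), ("e", "r_E")):
            denom = np.sqrt(t[f"V({comp})_tr1"] * t[f"V({comp})_tr2"])
            if denom > 0.05:  # identity is ill-conditioned for tiny components
                r = t[f"C({comp})_tr12"] / denom
                out.append((f"twin_{label}_identity", abs(r - t[label]) <= tol))
    return out
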