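# Methods

## The two estimation routes

### Bivariate GREML

For traits $y_1, y_2$ measured on (possibly overlapping) sets of
individuals with a genomic relationship matrix $A$,

$$y_t = X_t b_t + g_t + e_t, \qquad
\mathrm{Cov}\begin{pmatrix} g_1 \\ g_2 \end{pmatrix}
 = \begin{pmatrix} V_{G1} & C_{G12} \\ C_{G12} & V_{G2}\end{pmatrix} \otimes A,
\qquad
\mathrm{Cov}\begin{pmatrix} e_1 \\ e_2 \end{pmatrix}
 = \begin{pmatrix} V_{e1} & C_{e12} \\ C_{e12} & V_{e2}\end{pmatrix} \otimes I .$$

Residual covariance applies only within the same individual.  The six
components maximize the REML log-likelihood

$$\log L = -\tfrac12\left[\log|V| + \log|X^\top V^{-1}X| + y^\top P y\right],
\qquad P = V^{-1} - V^{-1}X(X^\top V^{-1}X)^{-1}X^\top V^{-1}.$$

**Assumptions.** Additive effects only; effect sizes i.i.d. on the
standardized-genotype scale (so every SNP contributes equally per unit of
$2p(1-p)$ heterozygosity); individuals unrelated beyond the GRM's sampling
noise; multivariate-normal phenotypes after preprocessing.

**GRM.** $A_{jk} = \frac{1}{M_{jk}}\sum_i \frac{(x_{ij}-2p_i)(x_{ik}-2p_i)}
{2p_i(1-p_i)}$ with $p_i$ the sample allele frequency and $M_{jk}$ the
pairwise-complete SNP count (mean imputation optional).  Allele frequencies
come from the analysis sample itself.  Note a consequence of
sample-frequency centering: the GRM's entries sum to zero, so the mean
off-diagonal is $\approx -1/(n-1)$, not 0.

**Optimization.** One EM-REML step, then average-information (AI) Newton
updates; convergence at $|\Delta\log L| < 10^{-8}$, cap 100 iterations
(both configurable).  The AI matrix is bent ($+\varepsilon I$,
$\varepsilon = 10^{-6}\,\mathrm{tr}$, doubling) when not invertible, and
steps are halved when they would decrease $\log L$ or leave the
positive-definite region.  Components are *unconstrained* (negative
estimates are reported and flagged, not clamped) because constraining
biases the standard errors.  When no valid ascending AI step exists — the
optimum can sit on the boundary of the PD region, e.g. a residual
covariance matrix going singular, and pairwise-complete GRMs need not even
be PSD — the climb is finished by Nelder-Mead on the same objective, and
an estimate landing near a component boundary triggers refits from four
deterministic perturbed starts (keeping the best likelihood), since
boundary ridges can carry multiple local maxima.  Starting values give
half the phenotypic (co)variance to each side; a starting genetic
correlation at or past ±1 is sanitized to ±0.5.

**Complexity.** When both traits are observed on the same individuals, one
eigendecomposition of $A$ makes the likelihood factor into $2\times 2$
blocks per eigenvalue, so each AI iteration is $O(np^2)$; a bivariate fit
at $n = 2000$ takes seconds.  Non-identical trait samples fall back to the
dense stacked model ($O(n^3)$ per iteration, full-information), intended
for moderate $n$.

**Standard errors.** The 6×6 inverse AI matrix at the optimum is the
sampling covariance of the components.  Correlations of components
($r_G = C_{G12}/\sqrt{V_{G1}V_{G2}}$, likewise $r_E$) get delta-method
SEs from the corresponding 3×3 block, written as a quadratic form
$g^\top \Sigma g$ with $g = (-r/2V_1,\ 1/\sqrt{V_1V_2},\ -r/2V_2)$.  The
published per-term expansion of this variance for $r_E$ (whose printed
transcription contains a garbled token, reproduced verbatim below for the
record) is algebraically identical, but the quadratic form needs no
special-casing at $C_e = 0$:

> Var(re) = re × re × (VarVe1/(4 × Ve1 × Ve1) + VarVe2/(4 × Ve2 × EV) +
> VarCe/(Ce × Ce) + CovVe1Ve2/(2 × Ve1 × Ve2 − CovVe1Ce/(Ve1 × Ce) −
> CovVe2Ce/(Ve2 × Ce)); SE(re) = sqrt[Var(re)]

The same delta-method pattern is applied to $r_G$, heritabilities and
phenotypic variances.  Calibration is verified empirically: across 200
simulated replicates at $n = 500$ the empirical SD of $\hat r_G$ matches
the mean delta-method SE within 25%, and a parametric bootstrap check on
toy instances matches the $r_E$ SE.

### Bivariate Cholesky ACE (twins)

Trait covariance is partitioned as $\Sigma_A = aa^\top$,
$\Sigma_C = cc^\top$, $\Sigma_E = ee^\top$ with $a, c, e$ lower-triangular
2×2 (PSD by construction).  A twin pair's 4-vector is multivariate normal
with within-person blocks $\Sigma_A+\Sigma_C+\Sigma_E$ and cross-twin
blocks $\Sigma_A+\Sigma_C$ (MZ) or $\tfrac12\Sigma_A+\Sigma_C$ (DZ,
additive coefficient fixed at ½, no assortative-mating adjustment;
same-sex and opposite-sex DZ pairs are pooled and no sex-limitation model
is fitted).  One free mean per trait is shared across twin order and
zygosity, which matches pre-residualized inputs.  Pairs with missing cells
contribute their observed sub-vector's likelihood (FIML), vectorized by
grouping pairs on missingness pattern.

Optimization: BFGS with numerical gradients from a moment-based start
($\Sigma_A = 2(\mathrm{MZ}-\mathrm{DZ})$ cross-twin covariances, etc.,
projected to PSD), plus seeded random restarts (default 5) and a
Nelder-Mead polish; the reported solution is the lowest $-2\ln L$.  The
Cholesky factors' column signs are not identified, so the canonical
reported form has nonnegative diagonals.  SEs come from the numerical
Hessian of $-\ln L$; derived quantities (standardized components,
$r_G/r_C/r_E$) get delta-method SEs through numerical gradients.  For two
traits the Cholesky and correlated-factors parameterizations are
likelihood-equivalent; the fit reports the path matrices *and* the
correlated-factors quantities rather than choosing.

Standardization divides per-trait components by the fitted phenotypic
variance and cross-trait components by $\sqrt{V_{p1}V_{p2}}$, so the three
standardized covariance components sum to the fitted phenotypic
correlation exactly.

`fit_from_moments` fits the same model to population moment matrices as
sufficient statistics; fed exact ACE-representable moments it reproduces
them to $10^{-6}$ (used as a noise-free oracle in the tests).

## Preprocessing

Applied per test score, in this order: single-pass ±3 SD outlier exclusion
(on raw scores; k configurable) → OLS regression on sex and age with
standardized residuals (complete-case) → van der Waerden quantile
normalization $\Phi^{-1}(r/(n+1))$ with average ranks for ties →
unit-weighted composite requiring a minimum number of observed tests
(e.g. 3-of-4 or 2-of-3).  Anthropometric traits skip the quantile step
(`quantile=False`).  One-per-family selection draws uniformly per family
from a seeded generator.  In the mixed-model stage the default covariates
are the Tracy–Widom-selected ancestry axes only (sex/age having been
regressed out already); a flag adds them again.

## GRM hygiene: relatedness and LD pruning

Relatedness pruning greedily drops the individual in the most
over-threshold pairs (ties → higher index) until no retained off-diagonal
exceeds the cutoff (default 0.025, roughly fourth-cousin similarity).
**Caveat:** the cutoff only makes sense when GRM sampling noise
($\mathrm{SD} \approx 1/\sqrt{m}$) is well below it, i.e. $m \gg 1600$
SNPs; the pipeline warns when the threshold is under $3/\sqrt{m}$, and the
small simulated test cohorts use a proportionally higher cutoff.  LD
pruning slides a window (default 50 SNPs, step 5 — only the $r^2 > 0.2$
cutoff is externally specified) and keeps the earlier-positioned SNP of
any conflicting pair.

## Tracy–Widom axis selection

PCA is the eigendecomposition of $(1/m)WW^\top$ on the relatedness- and
LD-pruned, column-standardized dosages.  Each leading eigenvalue is tested
sequentially: the remaining spectrum (size $N$, sums $S_1, S_2$) gives the
moment estimate of the effective column dimension
$\hat v = (N+2)S_1^2/(NS_2-S_1^2)$, the top eigenvalue is normalized as
$\ell = N\lambda_1/S_1$ and centred/scaled with the Tracy–Widom constants
for an $\hat v \times N$ white Wishart.  p-values come from an embedded
TW₁ quantile table generated once from the Chiani shifted-gamma
approximation (accurate to ~10⁻² in the quantile; e.g. 0.979 at p = 0.05
vs the exact 0.9793), linearly interpolated in $\log p$ and clamped to
$[10^{-6}, 0.5]$.  Selection keeps leading axes with $p < \alpha$
(default 0.05) and stops at the first non-significant axis.  Under a pure
noise spectrum the top-axis test rejects at ≈3–5% at $\alpha = 0.05$
(slightly conservative).

## The synthetic cohort generator

The generator emulates a cohort of a few thousand unrelated adolescents
genotyped at thousands of *independent* biallelic SNPs: ancestral MAFs
uniform on (0.05, 0.5), optional two-or-more-subpopulation structure via
Balding–Nichols $\mathrm{Beta}$ frequencies at a given $F_{ST}$, two
traits driven by a shared uniformly-drawn causal set with effect vectors
$\sim \mathrm{MVN}(0, \Sigma_G/n_{\text{causal}})$ on standardized
dosages, residuals $\sim \mathrm{MVN}(0, \Sigma_E)$.  Default component
scale: $\Sigma_G = [[0.36, 0.29], [0.29, 0.35]]$,
$\Sigma_E = [[0.63, 0.33], [0.33, 0.65]]$ — per-trait $h^2 \approx 0.36$
and true $r_G \approx 0.82$, the scale of published DNA-based estimates
for cognitive trait pairs at this cohort size.  Twin pairs are drawn from
the exact 4-variate normal of the ACE model; the default path matrices are
the Cholesky factors of published-scale standardized twin components
(true $r_G \approx 0.77$).  Missingness injection is an optional
missing-at-random post-step.

What the generator does **not** emulate — and hence what a green test does
not establish: linkage disequilibrium and haplotype structure (LD pruning
is exercised with planted duplicate/correlated columns instead),
imputation uncertainty, genotyping batch artefacts, X-chromosome and
non-additive (dominance/epistatic/GxE) effects, assortative mating, and
selection/attrition.  Because the generator matches the GREML model
exactly, recovery tests validate the *estimator*, not the model's fit to
real cohorts.

## Numerical choices and toy-instance design

- REML convergence $10^{-8}$ in $\log L$, cap 100 iterations; twin fits
  BFGS `gtol` $10^{-7}$ then Nelder-Mead polish.
- Ties in ranking: average ranks (standard van der Waerden convention).
- PCA axis signs fixed by making each axis's largest-magnitude loading
  positive.
- Relatedness-pruning ties drop the higher index — deterministic output.
- Oracle-equivalence tests compare AI-REML against multi-start Nelder-Mead
  on the *same* objective.  The toy instances use a family-structured
  relatedness matrix (sib pairs at 0.5/0.25 plus singletons) with
  phenotypes drawn exactly from the model: at $n = 30$ such instances have
  an interior, unimodal optimum with high probability, whereas a GRM built
  from a handful of SNPs routinely yields boundary/multimodal REML
  surfaces on which *no* two optimizers agree reliably.
- Unconstrained REML at small $n$ occasionally produces negative variance
  estimates (then $r_G$ is undefined and flagged as `nan` rather than
  clamped) and heavy-tailed correlation estimates; calibration checks
  therefore compare bulk spread (IQR-based) where tails are expected.

## Known limitations

- Two traits only; no multi-trait (>2) or genomic-partitioning models.
- The dense full-information path is $O(n^3)$ per iteration; very large
  cohorts with badly overlapping trait samples will be slow.
- No liability-threshold (binary trait) support in either route.
- The Tracy–Widom table's $10^{-6}$ floor caps reported significance of
  very strong structure axes (selection is unaffected).
- Greedy relatedness pruning approximates, not solves, minimum vertex
  cover; it matches the exact solution on the tested graph motifs.
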