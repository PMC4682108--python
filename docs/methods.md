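# Methods

This note documents the statistical model, the numerical choices, the
synthetic-data design and the known limitations of the package.

## Model and estimation

The univariate mixed linear model is `y = Xβ + g + e` with
`cov(g) = G σ²_g`, `cov(e) = I σ²_e` and `G = ZZ'/M` computed from
standardized genotypes.  `X` always carries an intercept as its first
column.  The restricted log-likelihood reported and maximized is

    lR(σ²_g, σ²_e) = −½ [ log|V| + log|X'V⁻¹X| + y'Py ],
    V = Gσ²_g + Iσ²_e,   P = V⁻¹ − V⁻¹X(X'V⁻¹X)⁻¹X'V⁻¹,

omitting the additive constant −((N−c)/2)·log 2π identically in every code
path, so values from different fitters are directly comparable.

### Diagonalized representation

All traces and quadratic forms are evaluated in a basis in which G is
diagonal: the eigenbasis of an explicit GRM, or the left singular basis of
Z when the GRM is given implicitly as ZZ'/M.  When rank(Z) = r < N, the
components of y and X lying in the null space of G are not discarded:
their Gram matrix is factored and appended as synthetic zero-eigenvalue
coordinates, and the remaining N − r − k dimensionless directions enter
only through log|V| and the degrees of freedom.  The representation is
therefore algebraically exact at any rank — the unit tests verify it
against dense-matrix constructions of V to ~1e-9 — and reduces the
per-iteration cost from O(N³) to O(N·c) after a one-off O(N·min(N,M)²)
factorization.  Eigenvalues of an explicit GRM that are slightly negative
from round-off are clipped at zero before fitting.

### AI-REML

Scores `s_k = −½[tr(P A_k) − y'P A_k P y]` (A₁ = G, A₂ = I) and the
average-information matrix `AI_kl = ½ y'P A_k P A_l P y` drive Newton-type
updates `θ ← θ + AI⁻¹s`.  Numerical policy:

* starting values: `σ²_g = σ²_e = var(y)/2`;
* step-halving (at most 10 halvings) whenever a step would decrease the
  restricted likelihood; if no fraction of the step improves it, iteration
  stops at numerical convergence;
* a singular AI matrix triggers a fallback to a step-halved gradient step;
* components are constrained to `ε = 1e-6 · var(y)`; an estimate at the
  constraint is reported with the `boundary` flag rather than raised;
* convergence: |Δ loglik| < 1e-6 and maximum relative parameter change
  < 1e-6; maximum 100 iterations, non-convergence flagged, not raised;
* standard errors from the inverse AI matrix at the optimum; the standard
  error of h² by the delta method.

The accepted-iteration log-likelihood path is recorded and is
non-decreasing by construction; a test asserts it.

### Eigen-rotation fast path

With δ = σ²_g/σ²_e the rotated covariance is `σ²_e · diag(δ d_k + 1)`.
GLS fixed effects and σ²_e are profiled out analytically
(`σ̂²_e(δ) = RSS_w/(N−c)` with weights `1/(δd_k+1)`), leaving a
one-dimensional problem solved by bounded Brent search over
log₁₀δ ∈ [−5, 5] with tolerance 1e-8.  The bracket covers h² from roughly
1e-5 to 1−1e-5 for typical eigenvalue scales.  A maximum at the lower
bracket edge is reported with σ²_g clamped to the same ε convention as
AI-REML, so the two paths agree on boundary cases too.  Standard errors
are computed from the AI matrix evaluated at the optimum.

The two fitters share only the diagonalized representation (which is
itself oracle-tested densely); their optimizers are independent, so their
agreement — asserted to 1e-4 relative on simulated instances, and against
a 2-D grid search on a 12-sample toy — is a genuine cross-check of both.

## Genotype handling

* PLINK 1 binary (.bed SNP-major, 2 bits per genotype, samples packed four
  per byte LSB-first; codes 00→2 copies of A1, 10→1, 11→0, 01→missing);
  trailing pad bits are written as zero, making round trips bit-exact.
* Standardization defaults to the Hardy–Weinberg s.d. `√(2p(1−p))` (the
  GCTA convention); the empirical s.d. is available via
  `compute_snp_stats(..., empirical_sd=True)`.  Both are exposed because
  field practice varies; the default is documented rather than silently
  assumed.
* Missing genotypes are mean-imputed (zero after standardization).  The
  GRM denominator is consequently the fixed SNP count M, never per-pair
  non-missing counts; this preserves the identity ĝ = Zâ exactly, which
  the BLUP tests rely on.
* The reference allele is PLINK A1 throughout; no strand flipping is ever
  attempted.  At scoring time alleles are reconciled per SNP: dosages are
  used as-is when the cohort's A1 matches the effect table's reference
  allele, flipped to 2−s when A2 matches, and rejected otherwise.
* Polygenic scores are reported centred (no intercept is added);
  correlation-based accuracy measures are translation invariant.

## Synthetic data

The generator emulates cohorts of unrelated individuals typed on a
biallelic array; it makes no attempt to reproduce any real population's
LD map.

* **Genotypes.**  Allele frequencies uniform on [0.05, 0.5] by default;
  dosages Binomial(2, p) (Hardy–Weinberg, linkage equilibrium) when
  `ld_rho = 0`.  For `ld_rho > 0` the genome is divided into independent
  LD blocks (50 SNPs by default) sharing one allele frequency; within a
  block each of the individual's two haplotypes follows a stationary
  two-state Markov chain with adjacent-site correlation exactly `ld_rho`.
  Equal within-block frequencies are deliberate: the maximum correlation
  between Bernoulli variables with different success probabilities is
  bounded (Fréchet), so heterogeneous frequencies would silently attenuate
  the requested LD.  Block boundaries model recombination hotspots; the
  measured mean adjacent-dosage correlation at ld_rho = 0.8 over 500 SNPs
  is ≈ 0.79.
* **Traits.**  A chosen number of QTNs receive independent standard-normal
  effects on the self-standardized genotype scale, giving every QTN equal
  expected variance regardless of allele frequency (the counterpart of the
  fitted model's `a ~ N(0, Iσ²_a)`); on the dosage scale effects therefore
  vary as u_j/σ_j.  Genetic values are rescaled to variance h² and the
  Gaussian residual is centred, projected exactly orthogonal to the
  genetic values, and rescaled to variance 1−h², so realized
  `var(g)/var(y)` equals the target h² to machine precision for every
  seed (variances with ddof = 0 throughout; the ratio is ddof-invariant).
  The orthogonal projection is essential for exactness — without it the
  empirical g–e covariance would perturb the ratio — and it also removes
  the attenuation bias that plagues unconditioned simulations: in a
  1,500-replicate calibration the mean REML ĥ² under this design was
  within 0.0008 of the target, while an unconditioned variant was biased
  low by ≈ 0.01 at N = 500.
* **Array scenarios.**  `partial_qtn` (all non-causal SNPs plus a random
  20% of QTNs — imperfect tagging), `all_qtn` (everything genotyped),
  `qtn_only` (causal variants only).
* All generators are pure functions of (spec, seed).

What passing tests on these data do **not** show: behaviour under real LD
(the AR(1) block model is far simpler than human LD), under population
structure or relatedness (individuals are exchangeable), under
maf-dependent genetic architectures, or with non-Gaussian residuals.

## Prediction experiments

`run_prediction_experiment` simulates a fresh cohort per (N_train,
replicate) cell, applies the array scenario, splits off a validation set
(default one ninth of N_train, i.e. a 90/10 split; a fixed validation size
can be requested so accuracy estimates are comparable across a grid of
training sizes), drops SNPs monomorphic in training, fits REML by the
eigen-rotation path, BLUPs SNP effects and scores the validation cohort.
Per-cell seeds derive from the master seed as
`(master·1000003 + 10007·cell + replicate) mod (2³¹−1)`, so any cell can
be reproduced alone.  Accuracy is summarized as the correlation of scores
with validation phenotypes (`r_pheno`, bounded by √h²) and with true
genetic values (`r_gen`).

For an architecture of M independent causal markers, classical theory
predicts `r²_gen ≈ N h²/(N h² + M)`, i.e. `1/r²_gen` linear in 1/N with
unit intercept and slope M/h².  `inverse_r2_regression` fits that line by
OLS to the per-N mean of 1/r²_gen; the test suite checks the intercept on
a qtn_only design (M = 500, h² = 0.5, N up to 8,000, measured intercept
≈ 0.97) and the 3,600-sample spot check against the closed form.  The
driver is capped at N ≤ 10,000 — grids of a few thousand individuals are
sufficient to exhibit the scaling laws while keeping a full experiment in
the minutes range on one core.

## GWAS and PCA

GWAS is deliberately plain per-SNP OLS of the phenotype on [covariates,
dosage] with complete-case handling per SNP and two-sided t-tests
(df = n_used − c − 1); no polygenic adjustment, genomic control or
multiple-testing correction is applied.  SNPs monomorphic among the used
samples are flagged (NaN estimates), and a numerically exact fit reports
the smallest positive double rather than p = 0.  PCA operates on the GRM
(equivalent to PCA of Z up to scaling); eigenvector signs follow the
convention that each component's largest-magnitude loading is positive,
and variance proportions use the positive part of the spectrum.

## Known limitations

* Single variance component only: no bivariate/multi-component REML, no
  regional partitioning, no dominance or epistatic relationship matrices.
* Dense linear algebra on a single node: cohorts beyond a few tens of
  thousands of samples are out of intended scope.
* PLINK 1 biallelic data only; no dosage/probability formats, no VCF.
* REML estimates at the lower constraint are reported with a boundary
  flag; no likelihood-ratio boundary correction is applied to their
  standard errors.
* The GWAS p-value floor and the AI-matrix-based standard errors are
  asymptotic devices; both are documented behaviours, not exact
  small-sample inference.
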