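# Methods

## Model and estimand

`sirtest` tests association between k SNP genotypes (minor-allele counts
g ∈ {0,1,2}^k) and q continuous traits y ∈ ℝ^q for n unrelated
individuals. The working generative model is multivariate linear,
Y = GB + E, with B the k×q effect matrix and error rows ε_i ~ (0, Σ); the
test itself is model-light because it conditions on an estimated
one-dimensional index of y.

The index comes from sufficient dimension reduction: assume
g ⟂ y | (S₁ᵀy, …, S_dᵀy) for a few directions S_m spanning the central
subspace. Sliced inverse regression estimates the standardized directions
as eigenvectors of Cov[E(z|g)], where z = Σ_yy^{−1/2}(y − E y). Under the
null of no association this matrix is 0 and cannot be decomposed stably,
so the estimator instead eigendecomposes the complementary matrix
E[Cov(z|g)] = I − Cov[E(z|g)] and takes the eigenvectors of its
*smallest* eigenvalues. Only the one-component case d₀ = 1 is used for
inference; the estimator itself accepts general d₀.

## Estimation conventions

* **Covariance divisors.** All covariances inside the SIR pipeline use the
  maximum-likelihood divisor: Σ̂_yy with divisor n, within-slice v̂_h with
  divisor n_h, slice weights p̂_h = n_h/n. With these choices the
  finite-sample law of total covariance

      Ê + Σ_h p̂_h z̄_h z̄_hᵀ = I     (Ê = Σ_h p̂_h v̂_h)

  holds exactly (the test suite asserts 1e−8; observed deviations are at
  machine precision). Mixed divisors (n−1 overall, n_h within) would break
  the identity by O(1/n), which is why the MLE convention is used
  throughout. Within-slice covariances are centered at the slice mean;
  singleton slices contribute a zero matrix, which is harmless since their
  weight multiplies zero variance.
* **Inverse square root.** Σ̂_yy^{−1/2} is computed by symmetric
  eigendecomposition. Eigenvalues below 1e−10 × (largest) raise a hard
  error rather than being pseudo-inverted: silently dropping a trait
  direction would change the null distribution of every downstream test.
  The caller is advised to remove collinear traits.
* **Sign and tie conventions.** Every eigenvector (SIR direction, PCA
  loading, GRM ordering vector) is sign-fixed by making its
  largest-magnitude coordinate positive; `numpy.linalg.eigh` supplies a
  deterministic ascending eigenvalue order. All test statistics are
  invariant to these conventions; they exist purely for reproducibility.

## Slicing

* **Exhaustive** (default for k < 10): one slice per *observed* genotype
  vector; unobserved patterns simply do not appear. A guard refuses
  3^k > 3^10 and points to the relatedness strategy.
* **Relatedness** (k ≥ 10): the GRM is the n×n correlation matrix of the
  individuals' genotype vectors. Individuals are ordered by their loading
  on its leading eigenvector (computed through the rank-k factor, O(nk²)),
  cut into contiguous blocks of `target_slice_size` (default 10), and
  blocks under `min_slice_size` (default 5) are merged left-to-right into
  their left neighbour (the first block merges rightward). The ordering
  rule had to be chosen here: a one-dimensional sort along the dominant
  relatedness axis is deterministic and gives "adjacent" a concrete
  meaning. Ties in the eigenvector (individuals with identical genotype
  vectors, or constant-genotype individuals, which receive loading 0) are
  broken by input order. `compute_grm` itself refuses individuals whose
  genotype vector is constant across SNPs, for whom correlation is
  undefined; the slicing path instead assigns them zero loading so that
  simulated datasets with such individuals remain analysable.

## Permutation inference

The null distribution of T̃ and T̃_j² is built by uniformly permuting the
rows of G, re-estimating the **whole** pipeline on each permuted dataset
(the reduction depends on G, so freezing it would not give an exchangeable
null), and using the add-one estimator p = (1 + #{T_b ≥ T_obs})/(1 + B).
p-values live on the grid {1/(B+1), …, 1} and never return 0. B defaults
to 1000; the simulation studies in this repository use B = 200.

Re-estimating the pipeline per permutation is algebraically cheap: the
trait standardization does not involve G; permuting G's rows permutes the
slice assignment and the GRM symmetrically; and XᵀX and the per-SNP
centered sums of squares are permutation-invariant. The permutation engine
therefore only regroups the fixed z-scores by a permuted assignment,
re-solves a q×q eigenproblem and re-runs two matrix–vector products per
permutation. The test suite verifies the engine against a literal re-fit.
One caveat: among individuals with *identical* genotype vectors the
engine's slice tie-break follows pre-permutation order while a literal
re-fit follows post-permutation order. Such individuals are exchangeable
given the data, so both conventions generate the same permutation null;
on tie-free data the two agree to machine precision.

SIR-S combines the k per-SNP permutation p-values by Bonferroni
(report min(1, k·p_j); reject if any adjusted p ≤ α). A SNP that is
constant in the sample gets p = 1 with a warning.

## Baselines

* **T1** (per SNP): multivariate OLS of all q traits on one SNP plus
  intercept; T1 = β̂_j[Cov(β̂_j)]⁻¹β̂_jᵀ referred to χ²_q. The "Wald"
  harness method applies T1 to every SNP with Bonferroni across SNPs.
* **T2** (joint): all kq slopes at once, computed as
  tr(Σ̂_e⁻¹ B̂ᵀ(G_cᵀG_c)B̂) and referred to χ²_{kq}.
* **PC-based tests**: centered PCA of Y (divisor n−1); per SNP, each PC
  score is tested by a simple-regression slope test (t², i.e. F(1, n−2)).
  PCA1 keeps the first PC's p-value; PCFisher refers −2Σ ln p_m to χ²_{2q}
  (treating PC p-values as independent, which is exact under multivariate
  normality since scores are uncorrelated); PCMinp applies Šidák across
  the q PCs. All three use Bonferroni across SNPs. These are standard
  forms matching the usual one-line sketches of the PC-combination
  family; further variants (PCLC, WI, VC, PCAQ) can be registered as
  plug-in callables but are not implemented here.

## Synthetic data

The generator emulates a population-based sequencing study: per SNP a MAF
p ~ U(0.3, 0.5) (drawn fresh each replicate), genotypes Binomial(2, p)
under Hardy–Weinberg equilibrium, independent across SNPs and individuals;
phenotypes Y = GB + E with ε_i ~ N(0, Σ), Σ_lm = ρ^{|l−m|},
ρ ∈ {0, 0.2, 0.5, 0.7} as presets. The preset effect matrices place a
strong effect (±1.10 on the first five traits) on SNP 3 and a weak effect
(0.02 on trait 2) on SNP 4, with all other rows zero; scenario 1 covers
(k, q) ∈ {5, 10}², scenario 2 high-dimensional traits (q = 50, 100,
k = 10), scenario 3 both high-dimensional (k = 40, 100; q = 50, 100).

What this does **not** emulate: linkage disequilibrium between SNPs, rare
variants (MAF < 0.3 by construction here), population structure or family
relatedness, non-Gaussian or heteroscedastic trait errors, missing data,
and covariates. Passing simulations therefore demonstrate calibration and
power under the stated generative law, not robustness to these real-data
features.

## Problem sizes in the shipped studies

The repository's own studies run at desk scale: 2,000 null replicates with
200 permutations per test for type-I error and p-value uniformity (a
±0.015 band around the reference rates, ≈3 binomial standard errors), 200
replicates for power, n = 5,000 vs n = 100,000 for direction recovery.
Paper-scale settings (100,000 replicates, 1,000 permutations) are
reachable through the config (`replicates`, `n_permutations`).

## Known limitations

* Inference is specified for d₀ = 1; multi-component testing would need a
  different statistic.
* The global model regresses ỹ on all SNPs jointly and requires
  n > k + 1 and a full-rank design; the per-SNP model ignores the other
  SNPs (no conditioning), as specified.
* The relatedness ordering uses only the leading GRM eigenvector; highly
  clustered genotype spaces may be poorly summarized by one axis.
* Permutation p-values are discrete with resolution 1/(B+1); family-wise
  Bonferroni on top of B = 200 permutations cannot reach adjusted
  p-values below k/201.
* Genotype allele orientation is taken as given in text input; VCF input
  counts alternate alleles with an explicit `flip_to_minor` option, since
  a 0↔2 recoding changes the slicing and hence the reduction.
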