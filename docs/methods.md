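# Methods

## Model and assumptions

`regfine` performs Bayesian variable selection over *causal
configurations* — subsets γ of the m variants in a region — under the
linear model

    y | λ ~ N(X_γ λ, σ²_γ I_n),    λ ~ N(0, s²_λ I_k),

with both phenotype and genotypes standardized (mean 0, variance 1 in the
1/n convention). Integrating λ analytically gives the marginal likelihood
N(y | 0, σ²_γ I + s²_λ X_γX_γ'), and the substitutions

    X_γ'X_γ = n R_γ,      X_γ'y = √n D_γ^{1/2} ẑ_γ,
    D = diag(σ²_ℓ),       σ²_ℓ = (1 + ẑ²_ℓ/n)^{-1},

turn it into a function of summary statistics only. These identities are
exact when the univariate summaries are computed with maximum-likelihood
conventions (no intercept on centered data, residual variance with 1/n),
which is how `summary_from_individual` computes them; for real GWAS
summaries computed with n−2 denominators the difference is O(1/n).

Key assumptions inherited from this construction:

- a single shared GWAS sample size n per region (the per-variant
  decomposition of D from beta/se alone is not identified otherwise);
- the LD matrix comes from the GWAS genotypes themselves, or is close to
  them — posterior quality degrades with LD mismatch;
- effects are additive on the standardized scale; the phenotype has unit
  variance, so λ'R_γλ is directly the regional heritability.

## Residual variances and the large-effect path

With small effects, σ²_γ ≈ 1 and the Bayes factor reduces to the earlier
unit-residual-variance derivation. When any variant individually explains
more than `large_effect_threshold` (default 0.01) of trait variance — i.e.
max_ℓ ẑ²_ℓ/(n+ẑ²_ℓ) > 0.01 — the configuration-specific ML residual
variance

    σ²_γ = 1 − u' R_γ^{-1} u / n,    u = D_γ^{1/2} ẑ_γ,

is used instead, clipped to [1e-4, 1] to avoid log(0) in pathological
configurations (clipping is effectively never active in realistic data and
is surfaced through the stored σ²_γ values).

In large-effect mode the effect-size prior variance is averaged over an
equidistant four-point grid on the s²_λ scale. The lower bound is 0.05²;
the upper bound is (√h²_γ*/2)², where h²_γ* = 1 − σ²_γ* for the greedy
*anchor configuration* γ*: variants with marginal heritability above the
threshold, taken in order of decreasing |ẑ| (ties broken by lowest index),
skipping any candidate with |r| ≥ 0.95 to an already-chosen one. The
factor 2 converts a 95% containment bound into a prior SD, mirroring the
0.05 ↔ 1% pairing of the baseline prior. If the bound does not exceed
0.05², the grid collapses to the single baseline value. The averaged Bayes
factor is the arithmetic mean over grid points (log-sum-exp), which
corresponds to a uniform prior over the grid.

## Priors over configurations

Pr(γ) = q_k / C(m, k), with q uniform over k = 1..K by default
(`k_prior` configurable, K = `max_causal`, default 10). The empty
configuration carries zero prior mass: the search is run on regions that
already show association, and PIPs/heritability are reported conditional
on at least one causal variant. The dimension prior of the released
fine-mapping tools is not public; uniform was chosen as the least
informative option and is exposed as a setting.

## Search

Shotgun stochastic search starts from the variant with the largest |ẑ|,
scores the full neighborhood (single-index deletions, additions, swaps) of
the current configuration with batched k×k Cholesky solves, caches scores
by index-set, and moves to a neighbor sampled proportionally to its
unnormalized posterior. The default budget is 100×m scored configurations
with a hard cap of 500 moves; both are configurable. Probabilities are
normalized over the explored set only; the unexplored mass is not
estimated. Configurations whose LD submatrix has condition number above
1e8 receive −∞ posterior weight rather than aborting the search. An exact
enumerator (`enumerate_exact`, refusing above 10^6 configurations) serves
as the search's oracle in tests.

## Effect and heritability posteriors

Per configuration and grid point, λ | data ~ N(μ, Σ) with
Σ = (s²_λ^{-1} I + n σ²_γ^{-1} R_γ)^{-1} and μ = √n σ²_γ^{-1} Σ u. The
regional heritability of a configuration is h² = λ'R_γλ, with point
estimate μ'R_γμ + tr(R_γΣ). The full posterior of h² is Monte Carlo over
the Bayesian-model-averaging mixture: draw a configuration by posterior
probability, a grid point by its Bayes-factor share within that
configuration, then λ, and evaluate λ'R_γλ. Defaults: 10,000 draws, seed
recorded in the output; the Monte Carlo error is far below the reported
posterior SD at these settings. Draws above 1 are retained (the quadratic
form has no hard bound; clipping would bias the interval) and counted in
`n_draws_above_one`.

Per-variant summaries come from the same mixture: *shrinkage* moments
treat the effect as exactly 0 in configurations excluding the variant, so
shrinkage_mean = PIP × conditional_mean holds as an exact identity;
*conditional* moments renormalize over including configurations and are
reported as NaN when PIP = 0.

## Fixed-effect baselines

The quadratic-form estimator is a reconstruction in the spirit of
fixed-effect local-heritability methods: with marginal standardized
effects b = ẑ/√n and the LD eigendecomposition,
ĥ² = (ẑ'R_q⁺ẑ − q)/(n − q), where R_q⁺ keeps the top q = min(50, m)
components ("truncated" mode) or all components with eigenvalue > 1e-8
("full" mode). The standard error is the large-n normal approximation
Var ≈ (n/(n−q))² (2q(1−h²)²/n² + 4h²(1−h²)/n) and is labeled approximate —
no exact variance formula is published for the reference implementation.

Stepwise conditional analysis reconstructs the joint-regression t-ratio of
each candidate given the selected set from summaries (using u = D^{1/2}ẑ
and the joint ML residual variance); this reduces to the familiar
(ẑ_j − R_jS R_SS^{-1} ẑ_S)/√(1 − R_jS R_SS^{-1}R_Sj) approximation for
small effects but stays within 2% of individual-level OLS t-ratios also at
moderate effect sizes. Selection stops below genome-wide significance
(P < 5×10⁻⁸ two-sided) or at `max_steps`; near-collinear candidates
(residual LD variance ≤ 1e-6) are skipped.

`lead_variant_h2` is the full pipeline with K = 1. `clump_regions` merges
±1 Mb windows around significant variants per chromosome, carrying the
minimum-P lead; an HLA interval flag (chr6:25–34 Mb, GRCh37) is provided
for exclusion workflows.

## Simulator

Genotypes follow a latent-Gaussian threshold model: two independent
haplotype-level latent matrices with AR(1) (default ρ = 0.9) or block
correlation, thresholded at the allele-frequency quantile (MAF drawn
uniformly, default [0.05, 0.5]) and summed to 0/1/2 dosages, then
standardized. This reproduces Hardy–Weinberg dosage frequencies and
distance-decaying LD; realized correlations are attenuated relative to the
latent ones by the discretization (strongly so at low MAF). It does not
reproduce features of real genotypes such as recombination hotspots,
long-range LD, haplotype structure, or allele-frequency/LD coupling — so
passing calibration tests demonstrate correctness of the inference under
the model class, not robustness to real-data artifacts such as LD
mismatch.

Phenotypes follow y = Σ_c β_c g_c + ε, ε ~ N(0, 1−h²), with
β_c = √(h² p_c) and sparse shares p = (0.618, 0.258, 0.124) for three
causal variants or equal shares otherwise; y is re-standardized so the
realized phenotype variance is exactly 1. Because β_c = √(h² p_c) yields
regional heritability h² only for uncorrelated causal variants,
`simulate_sparse_region` rescales the causal effect vector so that
β'R_γγβ = h² holds exactly (`normalize_h2=True` by default) — the regional
heritability is the quantity being fixed; the shares describe its
decomposition.

The fast path `rss_summary` draws z-scores directly:
z ~ N(√n R b_joint→marginal, R) by default, which matches individual-level
univariate regressions in distribution for small effects. With
`residual_adjust=True` (used by `simulate_sparse_region`) the exact
measurement model is used — per-variant D^{-1/2} scaling of the mean and
residual variance 1−h² on the noise — which stays unbiased also at
moderate heritability. Regions are realized with an LD genotype panel of
`n_ld` individuals (default 20,000) which may be smaller than the GWAS n:
the summary-statistic model is exactly specified by whatever R is
realized, so panel size is a realism/cost knob, not an approximation of
the method.

The rank-based inverse-normal transform maps covariate-regression
residual ranks r (average ties) to Φ^{-1}((r − 0.5)/n); the fixed 0.5
offset is a convention — any offset in (0, 1) preserves the stated
invariants (symmetry, monotone invariance, variance → 1).

## Numerical choices

- All configuration scoring goes through k×k Cholesky factorizations
  (batched over configurations grouped by k); the m×m matrix is never
  inverted.
- Condition-number cutoff 1e8 for LD submatrices; offending configurations
  get −∞ weight (search) or raise `DegenerateConfigurationError` (direct
  calls).
- σ²_γ floored at 1e-4; LD matrices validated to be symmetric (1e-10),
  unit-diagonal (exact), |r| ≤ 1+1e-8 and near-PSD (eigenvalues ≥ −1e-6).
- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; repeated runs are bit-identical, and CLI
  outputs are formatted (6 significant digits, probabilities at 4
  decimals) so reruns are byte-identical.

## Problem sizes used in the shipped studies

The calibration experiments run at desk scale by design: regions of
m = 200 variants (rather than the thousands in a 3 Mb biobank region), LD
panels of 20,000 individuals, 100 regions for the coverage study, and 20
replicates for the recovery and architecture-diagnostic studies. These
sizes keep the full study reproducible in minutes on one CPU while leaving
the Monte Carlo error well below the effect sizes being tested.

## Known limitations

- No allele harmonization, VCF/BGEN parsing or imputation: inputs are
  assumed pre-aligned (z file and LD matrix in the same variant order and
  allele coding).
- No functional-annotation priors, multi-ancestry LD mixing, credible-set
  construction, or variance-component (REML) polygenic baseline.
- The posterior is normalized over explored configurations; in very flat
  posteriors with small search budgets the normalization can be optimistic.
- The quadratic-form SE is approximate; its coverage is known to degrade
  exactly in the regimes the estimator itself is biased (strong truncation
  or strong regularization mismatch).
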