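"""Synthetic genotypes, phenotypes and GWAS summary statistics.

Genotypes follow a latent-Gaussian threshold model: two independent
haplotype-level latent Gaussian matrices with AR(1) (or block) correlation
are thresholded at the allele frequency quantile, so genotype dosages are
0/1/2 with Hardy-Weinberg proportions at the drawn MAFs and LD that decays
with distance (attenuated relative to the latent correlation by the
discretization). Phenotypes follow the sparse additive model
y = sum_c beta_c g_c + eps, eps ~ N(0, 1 - h2), with causal effects
beta_c = sqrt(h2 p_c) where p_c is the share of regional heritability.

The fast path draws marginal z-scores directly from the summary-statistic
model z ~ N(sqrt(n) R b, R), which agrees in distribution with z-scores
from individual-level univariate regressions for small effects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .summary_data import (
    GenotypeMatrix,
    InputError,
    LDMatrix,
    RegionSummary,
    Variant,
    ld_from_genotypes,
)

__all__ = [
    "ScenarioSpec",
    "simulate_genotypes",
    "assign_effects",
    "simulate_phenotype",
    "rss_summary",
    "preprocess_phenotype",
    "simulate_sparse_region",
]

SPARSE_PROPORTIONS = (0.618, 0.258, 0.124)


@dataclass(frozen=True)
class ScenarioSpec:
    """One simulation scenario cell: heritability, architecture, sample size."""

    h2: float
    m_causal: int
    n: int
    replicates: int = 10
    seed: int = 0
    proportions: tuple | None = None
    m: int = 200
    rho: float = 0.9
    maf_range: tuple = (0.05, 0.5)
    n_ld: int = 20_000

    def __post_init__(self) -> None:
        if not (0 < self.h2 < 1):
            raise ValueError(f"h2 must be in (0, 1), got {self.h2}")
        props = self.proportions
        if props is None:
            props = SPARSE_PROPORTIONS if self.m_causal == 3 else \
                tuple([1.0 / self.m_causal] * self.m_causal)
        props = tuple(float(p) for p in props)
        if len(props) != self.m_causal:
            raise ValueError("proportions length must equal m_causal")
        if abs(sum(props) - 1.0) > 1e-10:
            raise ValueError("proportions must sum to 1")
        object.__setattr__(self, "proportions", props)


def _latent_ar1(n: int, m: int, rho: float, rng) -> np.ndarray:
    x = np.empty((n, m))
    x[:, 0] = rng.standard_normal(n)
    scale = math.sqrt(1 - rho**2)
    for j in range(1, m):
        x[:, j] = rho * x[:, j - 1] + scale * rng.standard_normal(n)
    return x


def _latent_block(n: int, m: int, block_size: int, rho: float, rng) -> np.ndarray:
    x = np.empty((n, m))
    for start in range(0, m, block_size):
        stop = min(start + block_size, m)
        shared = rng.standard_normal(n)
        for j in range(start, stop):
            x[:, j] = math.sqrt(rho) * shared + math.sqrt(1 - rho) * \
                rng.standard_normal(n)
    return x


def simulate_genotypes(n: int, m: int, ld_model: str = "ar1", rho: float = 0.9,
                       maf_range=(0.05, 0.5), seed: int = 0,
                       block_size: int = 10):
    """Simulate standardized genotypes and their realized LD matrix.

    Two independent haplotype latents per individual are thresholded at the
    Hardy-Weinberg allele-frequency quantile so dosages are 0/1/2; columns
    are then standardized. Returns (GenotypeMatrix, LDMatrix, mafs).
    """
    lo, hi = maf_range
    if not (0.01 < lo <= hi <= 0.5):
        raise ValueError("maf_range must lie within (0.01, 0.5]")
    if ld_model == "ar1" and not (-1 < rho < 1):
        raise ValueError(f"AR(1) rho must be in (-1, 1), got {rho}")
    rng = np.random.default_rng(seed)
    mafs = rng.uniform(lo, hi, size=m)
    thresholds = stats.norm.ppf(1.0 - mafs)

    dosage = np.zeros((n, m), dtype=np.int8)
    for _hap in range(2):
        if ld_model == "ar1":
            latent = _latent_ar1(n, m, rho, rng)
        elif ld_model == "block":
            latent = _latent_block(n, m, block_size, rho, rng)
        else:
            raise ValueError(f"unknown ld_model {ld_model!r}")
        dosage += (latent > thresholds).astype(np.int8)

    try:
        g = GenotypeMatrix.from_raw(dosage.astype(float))
    except InputError:
        # monomorphic column at small n: nudge the lowest-MAF columns
        dosage = dosage.astype(float)
        for j in range(m):
            if dosage[:, j].std() == 0:
                dosage[rng.integers(n), j] = 1.0
        g = GenotypeMatrix.from_raw(dosage)
    return g, ld_from_genotypes(g), mafs


def assign_effects(h2: float, proportions) -> np.ndarray:
    """Causal effect sizes beta_c = sqrt(h2 * p_c) on the standardized scale."""
    p = np.asarray(proportions, dtype=float)
    if abs(p.sum() - 1.0) > 1e-10:
        raise ValueError("proportions must sum to 1")
    return np.sqrt(h2 * p)


def simulate_phenotype(g: GenotypeMatrix, causal_indices, betas, h2: float,
                       seed: int = 0) -> np.ndarray:
    """y = G_causal beta + eps with eps ~ N(0, 1 - h2), then standardized."""
    causal_indices = np.asarray(causal_indices, dtype=int)
    betas = np.asarray(betas, dtype=float)
    if causal_indices.size != betas.size:
        raise ValueError("causal indices and betas must have equal length")
    if np.any(causal_indices < 0) or np.any(causal_indices >= g.m):
        raise ValueError("causal index out of range")
    rng = np.random.default_rng(seed)
    y = g.g[:, causal_indices] @ betas
    y = y + rng.normal(0.0, math.sqrt(1.0 - h2), size=g.n)
    y = y - y.mean()
    return y / math.sqrt((y**2).mean())


def rss_summary(ld: LDMatrix, betas_marginal, n: int, seed: int = 0,
                mafs=None, chromosome: str = "1", positions=None,
                residual_adjust: bool = False,
                h2: float | None = None) -> RegionSummary:
    """Draw marginal z-scores from the summary-statistic model.

    By default z ~ N(sqrt(n) * betas_marginal, R), the standard small-effect
    form. With ``residual_adjust`` the draw follows the exact univariate
    measurement model for a phenotype with heritability ``h2``:
    z = (sqrt(n) b_marg + sqrt(1 - h2) * R^{1/2} eps) / sigma_l, where
    sigma_l^2 = 1 - b_marg,l^2 is the per-variant residual variance; the two
    agree for small effects. ``betas_marginal`` must be R @ beta_joint, the
    marginal standardized effects. Effect estimates and standard errors are
    back-computed from z under the ML convention (se = sqrt(1/(n + z^2))).
    """
    m = ld.m
    b = np.asarray(betas_marginal, dtype=float)
    if b.shape != (m,):
        raise ValueError("betas_marginal length must match LD dimension")
    rng = np.random.default_rng(seed)
    r = ld.r + 1e-10 * np.eye(m)
    try:
        chol = np.linalg.cholesky(r)
    except np.linalg.LinAlgError as exc:
        raise ValueError("LD matrix is not positive semi-definite") from exc
    noise = chol @ rng.standard_normal(m)
    if residual_adjust:
        if h2 is None:
            raise ValueError("residual_adjust requires the generative h2")
        d_half = np.sqrt(np.maximum(1.0 - b**2, 1e-8))
        z = (math.sqrt(n) * b + math.sqrt(1.0 - h2) * noise) / d_half
    else:
        z = math.sqrt(n) * b + noise
    se = np.sqrt(1.0 / (n + z**2))
    beta = z * se
    if mafs is None:
        mafs = np.full(m, 0.25)
    if positions is None:
        positions = np.arange(1, m + 1) * 1000
    variants = tuple(
        Variant(id=f"rs{j + 1}", chromosome=chromosome, position=int(positions[j]),
                allele1="A", allele2="G", maf=float(mafs[j]),
                beta=float(beta[j]), se=float(se[j]))
        for j in range(m)
    )
    return RegionSummary(variants=variants, ld=ld, n=n)


def preprocess_phenotype(raw, covariates=None) -> np.ndarray:
    """Residualize on covariates, then rank-inverse-normal transform.

    Residuals of the least-squares fit (with intercept) are mapped through
    ranks r (average ties) to Phi^{-1}((r - 0.5)/n), yielding an
    approximately standard-normal vector.
    """
    y = np.asarray(raw, dtype=float)
    n = y.shape[0]
    if covariates is not None:
        x = np.column_stack([np.ones(n), np.asarray(covariates, dtype=float)])
        if np.linalg.matrix_rank(x) < x.shape[1]:
            raise ValueError("covariate matrix is rank-deficient")
        coef, *_ = np.linalg.lstsq(x, y, rcond=None)
        y = y - x @ coef
    ranks = stats.rankdata(y, method="average")
    return stats.norm.ppf((ranks - 0.5) / n)


def simulate_sparse_region(m: int = 200, n: int = 50_000, h2: float = 0.05,
                           m_causal: int = 3, proportions=None,
                           rho: float = 0.9, maf_range=(0.05, 0.5),
                           n_ld: int = 20_000, seed: int = 0,
                           normalize_h2: bool = True):
    """One simulated region: realized LD from a genotype panel plus summary
    statistics drawn from the z-score model at GWAS sample size ``n``.

    When ``normalize_h2`` (default), the causal effect vector is rescaled so
    the realized regional heritability beta' R_cc beta equals ``h2`` exactly,
    which keeps the nominal heritability exact even when randomly placed
    causal variants land in LD with each other.

    Returns (RegionSummary, truth dict).
    """
    rng = np.random.default_rng(seed)
    s_geno, s_z = int(rng.integers(2**31)), int(rng.integers(2**31))
    _g, ld, mafs = simulate_genotypes(n_ld, m, rho=rho, maf_range=maf_range,
                                      seed=s_geno)
    if proportions is None:
        proportions = SPARSE_PROPORTIONS if m_causal == 3 else \
            np.full(m_causal, 1.0 / m_causal)
    causal = np.sort(rng.choice(m, size=m_causal, replace=False))
    beta_c = assign_effects(h2, proportions)
    sub = ld.submatrix(causal)
    realized = float(beta_c @ sub @ beta_c)
    if normalize_h2:
        beta_c = beta_c * math.sqrt(h2 / realized)
        realized = h2
    beta_joint = np.zeros(m)
    beta_joint[causal] = beta_c
    marginal = ld.r @ beta_joint
    region = rss_summary(ld, marginal, n, seed=s_z, mafs=mafs,
                         residual_adjust=True, h2=realized)
    truth = {
        "causal": causal,
        "beta": beta_c,
        "h2": realized,
        "h2_nominal": h2,
        "seed": seed,
    }
    return region, truth
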