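"""Effect-size and regional-heritability posteriors by model averaging.

For a configuration gamma with residual variance sigma2 and prior variance
s2, the joint standardized effects have the conjugate Gaussian posterior

    lambda | data ~ N(mu, Sigma),
    Sigma = (s^-2 I + n sigma^-2 R_gamma)^-1,
    mu    = sqrt(n) sigma^-2 Sigma D_gamma^{1/2} z_gamma.

Regional heritability of a configuration is h2 = lambda' R_gamma lambda
(variance explained by the causal variants on the standardized scale); its
posterior point estimate is mu'R mu + tr(R Sigma) and its full posterior is
obtained by Monte Carlo over the configuration mixture. In large-effect
regions the mixture also spans the prior-variance grid, with each grid
point weighted by its Bayes-factor share within the configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import ResidualVariances
from .search import ConfigurationPosterior, pip as _pip
from .summary_data import RegionSummary

__all__ = [
    "EffectPosterior",
    "HeritabilitySummary",
    "VariantEffectSummary",
    "effect_posterior",
    "heritability_point",
    "heritability_posterior",
    "variant_summaries",
]


@dataclass(frozen=True)
class EffectPosterior:
    """Gaussian posterior N(mu, sigma) of a configuration's joint effects."""

    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        mu = np.atleast_1d(np.asarray(self.mu, dtype=float))
        sigma = np.atleast_2d(np.asarray(self.sigma, dtype=float))
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "sigma", sigma)
        if not np.allclose(sigma, sigma.T):
            raise ValueError("posterior covariance must be symmetric")
        if np.any(np.linalg.eigvalsh(sigma) <= 0):
            raise ValueError("posterior covariance must be positive definite")


@dataclass(frozen=True)
class HeritabilitySummary:
    """Posterior mean, SD and equal-tail 95% credible interval of regional h2."""

    mean: float
    sd: float
    ci95: tuple
    draws_used: int
    seed: int
    n_draws_above_one: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.ci95
        if lo > hi:
            raise ValueError("credible interval bounds out of order")


@dataclass(frozen=True)
class VariantEffectSummary:
    """Model-averaged per-variant effect summary.

    Shrinkage moments treat the effect as exactly zero in configurations
    excluding the variant; conditional moments renormalize over including
    configurations (absent, as NaN, when PIP = 0).
    """

    index: int
    rsid: str
    pip: float
    shrinkage_mean: float
    shrinkage_sd: float
    conditional_mean: float
    conditional_sd: float


def _posterior_moments(idx, region, resid, s_lambda2, sigma2_gamma):
    idx = np.asarray(sorted(idx), dtype=int)
    n = region.n
    sub = region.ld.submatrix(idx)
    u = (resid.d_half * region.z)[idx]
    prec = np.eye(idx.size) / s_lambda2 + (n / sigma2_gamma) * sub
    chol = np.linalg.cholesky(prec)
    sigma = np.linalg.inv(prec)
    sigma = 0.5 * (sigma + sigma.T)
    mu = (math.sqrt(n) / sigma2_gamma) * (sigma @ u)
    return mu, sigma, chol


def effect_posterior(indices, region: RegionSummary, resid: ResidualVariances,
                     s_lambda2: float, sigma2_gamma: float) -> EffectPosterior:
    """Conjugate posterior of the joint effects of one configuration."""
    try:
        mu, sigma, _ = _posterior_moments(indices, region, resid,
                                          s_lambda2, sigma2_gamma)
    except np.linalg.LinAlgError as exc:
        from .model import DegenerateConfigurationError

        raise DegenerateConfigurationError(
            f"posterior precision for {tuple(indices)} is not positive definite"
        ) from exc
    return EffectPosterior(mu=mu, sigma=sigma)


def heritability_point(effect: EffectPosterior, ldsub: np.ndarray) -> float:
    """E[lambda' R lambda] = mu'R mu + tr(R Sigma) for one configuration."""
    ldsub = np.atleast_2d(np.asarray(ldsub, dtype=float))
    if ldsub.shape[0] != effect.mu.size:
        raise ValueError("LD submatrix shape does not match effect dimension")
    return float(effect.mu @ ldsub @ effect.mu + np.trace(ldsub @ effect.sigma))


def _grid_weights(posterior: ConfigurationPosterior) -> np.ndarray:
    """Per-configuration weights over the prior-variance grid (BF shares)."""
    glbf = posterior.grid_log_bf
    mx = glbf.max(axis=1, keepdims=True)
    w = np.exp(glbf - mx)
    return w / w.sum(axis=1, keepdims=True)


def heritability_posterior(posterior: ConfigurationPosterior,
                           region: RegionSummary, draws: int = 10_000,
                           seed: int = 0) -> HeritabilitySummary:
    """Monte Carlo posterior of regional h2 under the configuration mixture.

    Each draw samples a configuration by posterior probability, a grid
    point by its Bayes-factor share, then lambda from its Gaussian
    posterior, and evaluates lambda' R lambda. The null configuration
    contributes exactly 0. Draws above 1 are retained and counted, not
    clipped. Deterministic given ``seed``.
    """
    if draws < 1:
        raise ValueError("draws must be >= 1")
    rng = np.random.default_rng(seed)
    resid = ResidualVariances.from_region(posterior_region(posterior, region))
    counts = rng.multinomial(draws, posterior.probs)
    gw = _grid_weights(posterior)
    samples = np.empty(draws)
    pos = 0
    for ci in np.flatnonzero(counts):
        c = int(counts[ci])
        idx = posterior.index_sets[ci]
        if len(idx) == 0:
            samples[pos:pos + c] = 0.0
            pos += c
            continue
        sub = region.ld.submatrix(idx)
        gcounts = rng.multinomial(c, gw[ci])
        for gi in np.flatnonzero(gcounts):
            gc = int(gcounts[gi])
            mu, sigma, _ = _posterior_moments(
                idx, region, resid, float(posterior.grid[gi]),
                float(posterior.sigma2[ci]),
            )
            lam = rng.multivariate_normal(mu, sigma, size=gc, method="cholesky")
            samples[pos:pos + gc] = np.einsum("di,ij,dj->d", lam, sub, lam)
            pos += gc
    samples = samples[:pos]
    lo, hi = np.quantile(samples, [0.025, 0.975])
    return HeritabilitySummary(
        mean=float(samples.mean()),
        sd=float(samples.std(ddof=1)) if samples.size > 1 else 0.0,
        ci95=(float(lo), float(hi)),
        draws_used=int(samples.size),
        seed=seed,
        n_draws_above_one=int(np.sum(samples > 1.0)),
    )


def posterior_region(posterior: ConfigurationPosterior,
                     region: RegionSummary) -> RegionSummary:
    if region.m != posterior.m:
        raise ValueError("posterior and region describe different variant sets")
    return region


def variant_summaries(posterior: ConfigurationPosterior,
                      region: RegionSummary) -> list:
    """Model-averaged shrinkage and conditional effect summaries per variant.

    The shrinkage mixture places point mass at zero with probability
    1 - PIP, so shrinkage_mean = PIP * conditional_mean exactly.
    """
    posterior_region(posterior, region)
    resid = ResidualVariances.from_region(region)
    m = region.m
    mean_acc = np.zeros(m)
    m2_acc = np.zeros(m)
    gw = _grid_weights(posterior)

    # batch by (k): compute mu and diag(Sigma) for every config x grid point
    by_k: dict = {}
    for ci, idx in enumerate(posterior.index_sets):
        if idx:
            by_k.setdefault(len(idx), []).append(ci)

    n = region.n
    u_full = resid.d_half * region.z
    r_full = region.ld.r
    for k, cis in by_k.items():
        cis = np.asarray(cis, dtype=int)
        idx_arr = np.array([posterior.index_sets[c] for c in cis], dtype=int)
        sub = r_full[idx_arr[:, :, None], idx_arr[:, None, :]]
        u = u_full[idx_arr]
        s2g = posterior.sigma2[cis]
        for gi, s2 in enumerate(posterior.grid):
            prec = np.eye(k)[None] / s2 + (n / s2g)[:, None, None] * sub
            sigma = np.linalg.inv(prec)
            mu = (math.sqrt(n) / s2g)[:, None] * np.einsum("bij,bj->bi", sigma, u)
            dvar = np.diagonal(sigma, axis1=1, axis2=2)
            w = posterior.probs[cis] * gw[cis, gi]
            np.add.at(mean_acc, idx_arr.ravel(), (w[:, None] * mu).ravel())
            np.add.at(m2_acc, idx_arr.ravel(),
                      (w[:, None] * (mu**2 + dvar)).ravel())

    pips = _pip(posterior, m)
    out = []
    for j in range(m):
        p = float(pips[j])
        sh_mean = float(mean_acc[j])
        sh_var = max(float(m2_acc[j]) - sh_mean**2, 0.0)
        if p > 0:
            c_mean = sh_mean / p
            c_var = max(float(m2_acc[j]) / p - c_mean**2, 0.0)
            c_sd = math.sqrt(c_var)
        else:
            c_mean = math.nan
            c_sd = math.nan
        out.append(
            VariantEffectSummary(
                index=j,
                rsid=region.variants[j].id,
                pip=p,
                shrinkage_mean=sh_mean,
                shrinkage_sd=math.sqrt(sh_var),
                conditional_mean=c_mean,
                conditional_sd=c_sd,
            )
        )
    return out
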