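"""Configuration-level Bayes factors from GWAS summary statistics.

The model for a causal configuration gamma (a subset of k variants) is a
Bayesian linear regression of the standardized phenotype y on the
standardized genotypes of the configuration's variants,

    y | lambda ~ N(X_gamma lambda, sigma2_gamma I_n),
    lambda     ~ N(0, s_lambda2 I_k),

whose marginal likelihood depends on individual-level data only through
X'X = n R_gamma and X'y = sqrt(n) D_gamma^{1/2} z_gamma, where R is the LD
matrix, z the vector of univariate z-scores and D the diagonal matrix of
univariate residual-variance estimates sigma_l^2 = (1 + z_l^2/n)^{-1}.
The Bayes factor against the empty configuration is

    BF(gamma) = sigma2_gamma^{-n/2} det(I + n s2/sigma2 R_gamma)^{-1/2}
                * exp{ n/2 - n/(2 sigma2) (1 - u'(sigma2/s2 I + n R)^{-1} u) }

with u = D^{1/2} z. In regions where some variant individually explains
more than ~1% of trait variance ("large-effect mode"), sigma2_gamma is the
ML residual variance of the joint regression and the Bayes factor is
averaged over an equidistant grid of four prior variances; otherwise
sigma2_gamma is fixed at 1 and a single prior sd of 0.05 is used, under
which a causal variant explains <1% of variance with probability ~0.95.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .summary_data import RegionSummary

__all__ = [
    "CausalConfiguration",
    "PriorSettings",
    "ResidualVariances",
    "DegenerateConfigurationError",
    "univariate_residual_variance",
    "detect_large_effects",
    "config_residual_variance",
    "log_bf",
    "build_prior_grid",
    "averaged_log_bf",
    "config_log_prior",
    "score_configurations",
]

SIGMA2_FLOOR = 1e-4
CONDITION_LIMIT = 1e8


class DegenerateConfigurationError(RuntimeError):
    """The configuration's LD submatrix is too ill-conditioned to score."""


@dataclass(frozen=True)
class CausalConfiguration:
    """A causal configuration: variant indices with its score components."""

    indices: tuple
    log_bf: float
    sigma2_gamma: float
    log_posterior_unnorm: float

    def __post_init__(self) -> None:
        idx = tuple(sorted(int(i) for i in self.indices))
        object.__setattr__(self, "indices", idx)
        if len(idx) == 0 and self.log_bf != 0.0:
            raise ValueError("null configuration must have log_bf == 0")
        if not (0 < self.sigma2_gamma <= 1):
            raise ValueError(f"sigma2_gamma must be in (0, 1], got {self.sigma2_gamma}")

    @property
    def k(self) -> int:
        return len(self.indices)


@dataclass(frozen=True)
class PriorSettings:
    """Priors and limits for the configuration model.

    ``prior_sd`` is the baseline effect-size prior standard deviation on the
    standardized scale (default 0.05); ``k_prior`` is the probability vector
    over configuration sizes 1..K (uniform by default); the configuration
    prior is Pr(gamma) = k_prior[k] / C(m, k).
    """

    max_causal: int = 10
    prior_sd: float = 0.05
    k_prior: np.ndarray | None = None
    large_effect_threshold: float = 0.01
    s_lambda2_grid: np.ndarray | None = None  # explicit grid overrides auto

    def __post_init__(self) -> None:
        if self.max_causal < 1:
            raise ValueError("max_causal must be >= 1")
        if self.k_prior is not None:
            kp = np.asarray(self.k_prior, dtype=float)
            if kp.shape != (self.max_causal,):
                raise ValueError("k_prior must have length max_causal")
            if abs(kp.sum() - 1) > 1e-10 or np.any(kp < 0):
                raise ValueError("k_prior must be a probability vector")
            object.__setattr__(self, "k_prior", kp)
        if self.s_lambda2_grid is not None:
            grid = np.asarray(self.s_lambda2_grid, dtype=float)
            if np.any(grid <= 0) or np.any(np.diff(grid) < 0):
                raise ValueError("s_lambda2_grid must be positive and nondecreasing")
            object.__setattr__(self, "s_lambda2_grid", grid)
        if not (0 < self.large_effect_threshold < 1):
            raise ValueError("large_effect_threshold must be in (0, 1)")

    def log_k_prior(self, k: int) -> float:
        if k < 1 or k > self.max_causal:
            return -np.inf
        if self.k_prior is None:
            return -math.log(self.max_causal)
        p = self.k_prior[k - 1]
        return math.log(p) if p > 0 else -np.inf


@dataclass(frozen=True)
class ResidualVariances:
    """Per-variant univariate residual-variance estimates and their roots."""

    per_variant: np.ndarray
    d_half: np.ndarray

    @classmethod
    def from_region(cls, region: RegionSummary) -> "ResidualVariances":
        z = region.z
        s2 = univariate_residual_variance(z, region.n)
        return cls(per_variant=s2, d_half=np.sqrt(s2))


def univariate_residual_variance(z, n: int):
    """ML residual variance of the univariate regression: (1 + z^2/n)^{-1}."""
    if n <= 0:
        raise ValueError(f"sample size must be positive, got {n}")
    z = np.asarray(z, dtype=float)
    out = 1.0 / (1.0 + z**2 / n)
    return float(out) if out.ndim == 0 else out


def detect_large_effects(region: RegionSummary, threshold: float = 0.01) -> bool:
    """True when some variant individually explains > ``threshold`` of variance.

    The per-variant heritability estimate is 1 - sigma_l^2 = z^2/(n + z^2).
    Returning False selects the small-effect path (sigma2_gamma fixed at 1,
    single prior sd 0.05).
    """
    if not (0 < threshold < 1):
        raise ValueError("threshold must be in (0, 1)")
    resid = ResidualVariances.from_region(region)
    return bool(np.max(1.0 - resid.per_variant) > threshold)


def _u_vector(region: RegionSummary, resid: ResidualVariances) -> np.ndarray:
    return resid.d_half * region.z


def config_residual_variance(indices, region: RegionSummary,
                             resid: ResidualVariances) -> float:
    """ML residual variance of the joint regression on the configuration.

    sigma2_gamma = 1 - u' R_gamma^{-1} u / n with u = D^{1/2} z, clipped to
    [1e-4, 1]. For k = 1 this reduces algebraically to sigma_l^2.
    """
    idx = np.asarray(sorted(indices), dtype=int)
    if idx.size == 0:
        return 1.0
    sub = region.ld.submatrix(idx)
    w = np.linalg.eigvalsh(sub)
    if w[0] <= 0 or w[-1] / w[0] > CONDITION_LIMIT:
        raise DegenerateConfigurationError(
            f"LD submatrix for {tuple(idx)} is ill-conditioned"
        )
    u = _u_vector(region, resid)[idx]
    quad = float(u @ np.linalg.solve(sub, u))
    return float(np.clip(1.0 - quad / region.n, SIGMA2_FLOOR, 1.0))


def log_bf(indices, region: RegionSummary, resid: ResidualVariances,
           s_lambda2: float, sigma2_gamma: float) -> float:
    """Log Bayes factor of a configuration against the null, via the k x k system."""
    idx = np.asarray(sorted(indices), dtype=int)
    k = idx.size
    if k == 0:
        return 0.0
    n = region.n
    sub = region.ld.submatrix(idx)
    u = _u_vector(region, resid)[idx]
    a = n * sub + (sigma2_gamma / s_lambda2) * np.eye(k)
    try:
        chol = np.linalg.cholesky(a)
    except np.linalg.LinAlgError as exc:
        raise DegenerateConfigurationError(
            f"inner matrix for {tuple(idx)} is not positive definite"
        ) from exc
    logdet_a = 2.0 * float(np.sum(np.log(np.diag(chol))))
    w = np.linalg.solve(chol, u)
    quad = float(w @ w)
    # det(I + n s2/sigma2 R) = (s2/sigma2)^k det(sigma2/s2 I + n R)
    logdet = k * math.log(s_lambda2 / sigma2_gamma) + logdet_a
    return (
        -(n / 2.0) * math.log(sigma2_gamma)
        - 0.5 * logdet
        + n / 2.0
        - (n / (2.0 * sigma2_gamma)) * (1.0 - quad)
    )


def _anchor_configuration(region: RegionSummary, resid: ResidualVariances,
                          threshold: float) -> list:
    """Greedy anchor: most significant variants with per-variant heritability
    above ``threshold`` and pairwise |r| < 0.95; ties broken by lowest index."""
    h2_marg = 1.0 - resid.per_variant
    candidates = np.flatnonzero(h2_marg > threshold)
    # sort by decreasing |z|; stable sort keeps lowest index first on ties
    order = candidates[np.argsort(-np.abs(region.z[candidates]), kind="stable")]
    chosen: list = []
    for j in order:
        if all(abs(region.ld.r[j, c]) < 0.95 for c in chosen):
            chosen.append(int(j))
    return chosen


def build_prior_grid(region: RegionSummary, resid: ResidualVariances,
                     settings: PriorSettings) -> np.ndarray:
    """Equidistant 4-point grid of prior variances for large-effect regions.

    The lower bound is 0.05^2. The upper bound s_up^2 uses
    s_up = sqrt(h2_anchor)/2 where h2_anchor = 1 - sigma2 of the greedy
    anchor configuration, pairing a 95% probability bound with the anchor
    heritability the same way 0.05 pairs with 1%. A degenerate bound
    (s_up^2 <= 0.05^2) collapses the grid to the single baseline value.
    """
    base = settings.prior_sd**2
    anchor = _anchor_configuration(region, resid, settings.large_effect_threshold)
    if not anchor:
        return np.array([base])
    h2_anchor = 1.0 - config_residual_variance(anchor, region, resid)
    s_up2 = h2_anchor / 4.0  # (sqrt(h2)/2)^2
    if s_up2 <= base:
        return np.array([base])
    return np.linspace(base, s_up2, 4)


def averaged_log_bf(indices, region: RegionSummary, resid: ResidualVariances,
                    grid, sigma2_gamma: float | None = None) -> float:
    """Log of the arithmetic mean of Bayes factors over the prior-variance grid."""
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("grid must be nonempty")
    if sigma2_gamma is None:
        sigma2_gamma = config_residual_variance(indices, region, resid)
    logs = np.array([log_bf(indices, region, resid, s2, sigma2_gamma) for s2 in grid])
    return float(logsumexp(logs) - math.log(grid.size))


def config_log_prior(k: int, m: int, settings: PriorSettings) -> float:
    """log Pr(gamma) = log k_prior[k] - log C(m, k)."""
    lp = settings.log_k_prior(k)
    if not np.isfinite(lp):
        return -np.inf
    return lp - (math.lgamma(m + 1) - math.lgamma(k + 1) - math.lgamma(m - k + 1))


def score_configurations(index_sets, region: RegionSummary,
                         resid: ResidualVariances, grid, settings: PriorSettings,
                         large_effects: bool):
    """Vectorized scoring of many configurations.

    Groups configurations by size k and evaluates sigma2_gamma and the
    per-grid-point log Bayes factors with batched k x k linear algebra.
    Ill-conditioned configurations (condition number > 1e8) receive
    -inf posterior weight instead of raising.

    Returns arrays aligned with ``index_sets``:
    (log_posterior_unnorm, avg_log_bf, grid_log_bf (N, G), sigma2, valid).
    """
    grid = np.asarray(grid, dtype=float)
    n_cfg = len(index_sets)
    n = region.n
    m = region.m
    g_len = grid.size
    u_full = _u_vector(region, resid)
    r_full = region.ld.r

    avg = np.full(n_cfg, -np.inf)
    grid_lbf = np.full((n_cfg, g_len), -np.inf)
    sigma2 = np.ones(n_cfg)
    valid = np.zeros(n_cfg, dtype=bool)
    log_post = np.full(n_cfg, -np.inf)

    by_k: dict = {}
    for pos, idx in enumerate(index_sets):
        by_k.setdefault(len(idx), []).append(pos)

    for k, positions in by_k.items():
        positions = np.asarray(positions, dtype=int)
        if k == 0 or k > settings.max_causal:
            # null or oversized: zero prior mass in the explored posterior
            if k == 0:
                avg[positions] = 0.0
                grid_lbf[positions] = 0.0
                valid[positions] = True
            continue
        idx_arr = np.array([index_sets[p] for p in positions], dtype=int)  # (B, k)
        sub = r_full[idx_arr[:, :, None], idx_arr[:, None, :]]  # (B, k, k)
        u = u_full[idx_arr]  # (B, k)

        w = np.linalg.eigvalsh(sub)
        ok = (w[:, 0] > 0) & (w[:, -1] <= CONDITION_LIMIT * w[:, 0])
        if not np.any(ok):
            continue
        sub_ok = sub[ok]
        u_ok = u[ok]
        b = sub_ok.shape[0]

        quad_r = np.einsum("bi,bi->b", u_ok, np.linalg.solve(sub_ok, u_ok[..., None])[..., 0])
        if large_effects:
            s2g = np.clip(1.0 - quad_r / n, SIGMA2_FLOOR, 1.0)
        else:
            s2g = np.ones(b)

        eye = np.eye(k)
        lbf_k = np.empty((b, g_len))
        for gi, s2 in enumerate(grid):
            a = n * sub_ok + (s2g / s2)[:, None, None] * eye
            chol = np.linalg.cholesky(a)
            logdet_a = 2.0 * np.sum(np.log(np.diagonal(chol, axis1=1, axis2=2)), axis=1)
            sol = np.linalg.solve(a, u_ok[..., None])[..., 0]
            quad = np.einsum("bi,bi->b", u_ok, sol)
            logdet = k * np.log(s2 / s2g) + logdet_a
            lbf_k[:, gi] = (
                -(n / 2.0) * np.log(s2g)
                - 0.5 * logdet
                + n / 2.0
                - (n / (2.0 * s2g)) * (1.0 - quad)
            )
        avg_k = logsumexp(lbf_k, axis=1) - math.log(g_len)

        pos_ok = positions[ok]
        sigma2[pos_ok] = s2g
        grid_lbf[pos_ok] = lbf_k
        avg[pos_ok] = avg_k
        valid[pos_ok] = True
        log_post[pos_ok] = avg_k + config_log_prior(k, m, settings)

    return log_post, avg, grid_lbf, sigma2, valid
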