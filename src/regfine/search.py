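"""Shotgun stochastic search over causal configurations.

The search walks the configuration space by scoring the full neighborhood
(single-index deletions, additions and swaps) of the current configuration
and moving to a neighbor sampled proportionally to its unnormalized
posterior. Scores are cached by index-set, so revisits are free, and the
returned posterior is normalized over all distinct configurations scored
during the walk — the search aims to capture a large majority of the total
posterior mass, and the unexplored remainder is not estimated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.special import logsumexp

from .model import (
    CausalConfiguration,
    PriorSettings,
    ResidualVariances,
    build_prior_grid,
    detect_large_effects,
    score_configurations,
)
from .summary_data import RegionSummary

__all__ = [
    "ConfigurationPosterior",
    "neighborhood",
    "sss_search",
    "enumerate_exact",
    "pip",
    "expected_num_causal",
]


@dataclass
class ConfigurationPosterior:
    """Explored causal configurations with normalized posterior probabilities.

    Parallel arrays over stored configurations: ``index_sets`` (tuples of
    variant indices), ``probs`` (normalized over the stored set),
    ``log_bf`` (grid-averaged), ``grid_log_bf`` (per grid point) and
    ``sigma2`` (configuration residual variances). ``grid`` holds the
    prior-variance grid the scores were averaged over.
    """

    index_sets: list
    probs: np.ndarray
    log_bf: np.ndarray
    grid_log_bf: np.ndarray
    sigma2: np.ndarray
    grid: np.ndarray
    large_effects: bool
    explored_count: int
    total_unnorm_mass: float  # log scale
    m: int
    settings: PriorSettings

    def __post_init__(self) -> None:
        if len(set(self.index_sets)) != len(self.index_sets):
            raise ValueError("duplicate configurations in posterior")
        if abs(self.probs.sum() - 1.0) > 1e-10:
            raise ValueError("posterior probabilities must sum to 1")

    @property
    def n_configs(self) -> int:
        return len(self.index_sets)

    def configuration(self, i: int) -> CausalConfiguration:
        return CausalConfiguration(
            indices=self.index_sets[i],
            log_bf=float(self.log_bf[i]),
            sigma2_gamma=float(self.sigma2[i]),
            log_posterior_unnorm=float(np.log(self.probs[i]) + self.total_unnorm_mass)
            if self.probs[i] > 0 else -np.inf,
        )

    def top(self, k: int = 10) -> list:
        order = np.argsort(-self.probs)[:k]
        return [(self.index_sets[i], float(self.probs[i])) for i in order]


def neighborhood(indices, m: int, max_causal: int) -> list:
    """All configurations one move away: delete, add (if k < K), or swap."""
    current = tuple(sorted(int(i) for i in indices))
    k = len(current)
    members = set(current)
    out = []
    for i in current:  # deletions
        out.append(tuple(x for x in current if x != i))
    non_members = [j for j in range(m) if j not in members]
    if k < max_causal:  # additions
        for j in non_members:
            out.append(tuple(sorted(current + (j,))))
    for i in current:  # swaps
        rest = tuple(x for x in current if x != i)
        for j in non_members:
            out.append(tuple(sorted(rest + (j,))))
    return out


class _Scorer:
    """Caching batch scorer for configurations of one region."""

    def __init__(self, region: RegionSummary, settings: PriorSettings):
        self.region = region
        self.settings = settings
        self.resid = ResidualVariances.from_region(region)
        self.large_effects = detect_large_effects(
            region, settings.large_effect_threshold
        )
        if settings.s_lambda2_grid is not None:
            self.grid = settings.s_lambda2_grid
        elif self.large_effects:
            self.grid = build_prior_grid(region, self.resid, settings)
        else:
            self.grid = np.array([settings.prior_sd**2])
        self.cache: dict = {}  # idx tuple -> (log_post, avg_lbf, grid_lbf, sigma2)
        self.evaluations = 0

    def score(self, index_sets) -> None:
        new = [s for s in dict.fromkeys(index_sets) if s not in self.cache]
        if not new:
            return
        log_post, avg, grid_lbf, sigma2, _valid = score_configurations(
            new, self.region, self.resid, self.grid, self.settings,
            self.large_effects,
        )
        for i, s in enumerate(new):
            self.cache[s] = (log_post[i], avg[i], grid_lbf[i], sigma2[i])
        self.evaluations += len(new)

    def log_post(self, index_sets) -> np.ndarray:
        return np.array([self.cache[s][0] for s in index_sets])

    def to_posterior(self, explored_count: int) -> ConfigurationPosterior:
        # keep only configurations with nonzero prior (1 <= k <= K)
        items = [(s, v) for s, v in self.cache.items() if np.isfinite(v[0])]
        if not items:
            raise RuntimeError("no configuration with finite posterior was scored")
        sets = [s for s, _ in items]
        log_post = np.array([v[0] for _, v in items])
        total = float(logsumexp(log_post))
        probs = np.exp(log_post - total)
        probs /= probs.sum()
        return ConfigurationPosterior(
            index_sets=sets,
            probs=probs,
            log_bf=np.array([v[1] for _, v in items]),
            grid_log_bf=np.vstack([v[2] for _, v in items]),
            sigma2=np.array([v[3] for _, v in items]),
            grid=self.grid,
            large_effects=self.large_effects,
            explored_count=explored_count,
            total_unnorm_mass=total,
            m=self.region.m,
            settings=self.settings,
        )


def sss_search(region: RegionSummary, settings: PriorSettings | None = None,
               iterations: int | None = None, seed: int = 0,
               max_evals: int | None = None) -> ConfigurationPosterior:
    """Shotgun stochastic search; deterministic given ``seed``.

    ``iterations`` is the number of moves; when None, the walk continues
    until roughly 100 x m configurations have been scored (capped at 500
    moves). The start point is the variant with the largest |z|.
    """
    settings = settings or PriorSettings()
    rng = np.random.default_rng(seed)
    m = region.m
    if iterations is not None and iterations < 1:
        raise ValueError("iterations must be >= 1")
    budget = max_evals if max_evals is not None else 100 * m
    max_moves = iterations if iterations is not None else 500

    scorer = _Scorer(region, settings)
    current = (int(np.argmax(np.abs(region.z))),)
    scorer.score([current])

    moves = 0
    while moves < max_moves:
        if iterations is None and scorer.evaluations >= budget:
            break
        nbrs = neighborhood(current, m, settings.max_causal)
        nbrs = list(dict.fromkeys(nbrs))
        scorer.score(nbrs)
        lp = scorer.log_post(nbrs)
        finite = np.isfinite(lp)
        if not np.any(finite):
            break
        w = np.zeros(len(nbrs))
        w[finite] = np.exp(lp[finite] - lp[finite].max())
        w /= w.sum()
        current = nbrs[int(rng.choice(len(nbrs), p=w))]
        moves += 1

    return scorer.to_posterior(explored_count=len(scorer.cache))


def enumerate_exact(region: RegionSummary,
                    settings: PriorSettings | None = None) -> ConfigurationPosterior:
    """Exact posterior over all configurations of size 1..K.

    Refuses when the total count exceeds 10^6 configurations.
    """
    settings = settings or PriorSettings()
    m = region.m
    total = sum(math.comb(m, k) for k in range(1, settings.max_causal + 1))
    if total > 10**6:
        raise ValueError(
            f"exhaustive enumeration of {total} configurations exceeds the 1e6 budget"
        )
    scorer = _Scorer(region, settings)
    sets = []
    for k in range(1, settings.max_causal + 1):
        sets.extend(combinations(range(m), k))
    scorer.score(sets)
    return scorer.to_posterior(explored_count=len(sets))


def pip(posterior: ConfigurationPosterior, m: int | None = None) -> np.ndarray:
    """Posterior inclusion probabilities: sum of probabilities of
    configurations containing each variant. Their total equals E(k)."""
    m = m if m is not None else posterior.m
    out = np.zeros(m)
    for s, p in zip(posterior.index_sets, posterior.probs):
        if s:
            np.add.at(out, list(s), p)
    return out


def expected_num_causal(posterior: ConfigurationPosterior) -> float:
    """Posterior expected configuration size, sum_gamma P(gamma) k(gamma)."""
    sizes = np.array([len(s) for s in posterior.index_sets])
    return float(posterior.probs @ sizes)
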