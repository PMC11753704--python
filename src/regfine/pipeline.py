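"""End-to-end fine-mapping of one region: search, PIPs, effects, h2."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .effects import (
    HeritabilitySummary,
    heritability_posterior,
    variant_summaries,
)
from .model import PriorSettings
from .search import (
    ConfigurationPosterior,
    enumerate_exact,
    expected_num_causal,
    pip,
    sss_search,
)
from .summary_data import RegionSummary

__all__ = ["RegionResult", "fine_map_region"]


@dataclass
class RegionResult:
    """Everything the fine-mapping pipeline reports for one region."""

    posterior: ConfigurationPosterior
    pips: np.ndarray
    h2: HeritabilitySummary
    expected_k: float
    large_effects: bool
    grid: np.ndarray
    summaries: list | None = None

    def variant_frame(self) -> pd.DataFrame:
        """Per-variant table: index rsid prob mean sd mean_incl sd_incl."""
        if self.summaries is None:
            raise ValueError("pipeline was run with compute_summaries=False")
        return pd.DataFrame(
            {
                "index": [s.index for s in self.summaries],
                "rsid": [s.rsid for s in self.summaries],
                "prob": [s.pip for s in self.summaries],
                "mean": [s.shrinkage_mean for s in self.summaries],
                "sd": [s.shrinkage_sd for s in self.summaries],
                "mean_incl": [s.conditional_mean for s in self.summaries],
                "sd_incl": [s.conditional_sd for s in self.summaries],
            }
        )


def fine_map_region(region: RegionSummary, max_causal: int = 10,
                    iterations: int | None = None, draws: int = 10_000,
                    seed: int = 0, large_effect_threshold: float = 0.01,
                    prior_sd: float = 0.05, exact: bool = False,
                    compute_summaries: bool = True,
                    settings: PriorSettings | None = None) -> RegionResult:
    """Fine-map one region from summary statistics.

    Runs the stochastic search (or exhaustive enumeration when ``exact``),
    then computes posterior inclusion probabilities, the Monte Carlo
    posterior of regional heritability, and, optionally, model-averaged
    per-variant effect summaries. All randomness derives from ``seed``.
    """
    if settings is None:
        settings = PriorSettings(
            max_causal=max_causal,
            prior_sd=prior_sd,
            large_effect_threshold=large_effect_threshold,
        )
    if exact:
        posterior = enumerate_exact(region, settings)
    else:
        posterior = sss_search(region, settings, iterations=iterations, seed=seed)
    h2 = heritability_posterior(posterior, region, draws=draws, seed=seed + 1)
    summaries = variant_summaries(posterior, region) if compute_summaries else None
    return RegionResult(
        posterior=posterior,
        pips=pip(posterior),
        h2=h2,
        expected_k=expected_num_causal(posterior),
        large_effects=posterior.large_effects,
        grid=posterior.grid,
        summaries=summaries,
    )
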