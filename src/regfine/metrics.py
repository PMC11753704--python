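"""Calibration metrics for heritability estimators: RMSE, interval coverage
and the reported-SD / empirical-SD ratio."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["EvalRecord", "rmse", "coverage", "sd_ratio", "summarize"]


@dataclass(frozen=True)
class EvalRecord:
    """One replicate's estimate, 95% interval and truth, with labels."""

    estimate: float
    interval: tuple
    truth: float
    method: str = ""
    scenario: str = ""

    def __post_init__(self) -> None:
        lo, hi = self.interval
        if lo > hi:
            raise ValueError("interval bounds out of order")


def rmse(records) -> float:
    """Root mean squared deviation of estimates from truth."""
    records = list(records)
    if not records:
        raise ValueError("rmse requires at least one record")
    dev = np.array([r.estimate - r.truth for r in records])
    return float(np.sqrt(np.mean(dev**2)))


def coverage(records) -> float:
    """Fraction of intervals containing the truth."""
    records = list(records)
    if not records:
        raise ValueError("coverage requires at least one record")
    hits = [r.interval[0] <= r.truth <= r.interval[1] for r in records]
    return float(np.mean(hits))


def sd_ratio(reported_sds, estimates) -> float:
    """mean(reported SD) / sample SD of the estimates.

    A frequentistically calibrated uncertainty report gives a ratio near 1.
    """
    reported_sds = np.asarray(reported_sds, dtype=float)
    estimates = np.asarray(estimates, dtype=float)
    if estimates.size < 2:
        raise ValueError("sd_ratio requires at least two estimates")
    sd = estimates.std(ddof=1)
    if sd == 0:
        raise ValueError("estimates have zero standard deviation")
    return float(reported_sds.mean() / sd)


def summarize(records) -> pd.DataFrame:
    """Per (scenario, method) summary: mean, SD, RMSE, coverage, sd_ratio.

    ``records`` is an iterable of EvalRecord, optionally carrying a
    reported SD via an (estimate, interval, truth, method, scenario) tuple
    plus interval half-width as proxy — here the interval is used for
    coverage and the estimate spread for the SD column.
    """
    records = list(records)
    df = pd.DataFrame(
        {
            "scenario": [r.scenario for r in records],
            "method": [r.method for r in records],
            "estimate": [r.estimate for r in records],
            "low": [r.interval[0] for r in records],
            "high": [r.interval[1] for r in records],
            "truth": [r.truth for r in records],
        }
    )
    rows = []
    for (scen, meth), grp in df.groupby(["scenario", "method"], sort=True):
        recs = [records[i] for i in grp.index]
        rows.append(
            {
                "scenario": scen,
                "method": meth,
                "n": len(recs),
                "mean": grp["estimate"].mean(),
                "sd": grp["estimate"].std(ddof=1) if len(recs) > 1 else 0.0,
                "rmse": rmse(recs),
                "coverage": coverage(recs),
            }
        )
    return pd.DataFrame(rows)
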