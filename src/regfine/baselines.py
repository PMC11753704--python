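"""Fixed-effect baselines: quadratic-form regional heritability, stepwise
approximate conditional analysis, lead-variant heritability, and clumping.

The quadratic-form estimator is a HESS-style reconstruction of local SNP
heritability from marginal standardized effects b = z/sqrt(n) and the LD
eigendecomposition: with R_q^+ the rank-q pseudo-inverse,

    h2 = (n b' R_q^+ b - q) / (n - q) = (z' R_q^+ z - q) / (n - q).

Default ("truncated") mode keeps the top min(50, m) principal components;
"full" mode keeps every component with eigenvalue above 1e-8. The standard
error is an approximate large-n normal form and is labeled as such.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .pipeline import RegionResult, fine_map_region
from .summary_data import RegionSummary

__all__ = [
    "QuadFormResult",
    "ClumpedRegion",
    "quadratic_form_h2",
    "stepwise_conditional",
    "lead_variant_h2",
    "clump_regions",
    "HLA_REGION",
]

# GRCh37 extended HLA interval used as an optional exclusion window
HLA_REGION = ("6", 25_000_000, 34_000_000)


@dataclass(frozen=True)
class QuadFormResult:
    h2: float
    q_used: int
    se: float
    mode: str

    def __post_init__(self) -> None:
        if self.q_used < 1:
            raise ValueError("q_used must be >= 1")


def quadratic_form_h2(region: RegionSummary, mode: str = "truncated",
                      max_eig: int = 50, min_eigval: float = 1e-8) -> QuadFormResult:
    """Regularized quadratic-form estimate of regional heritability."""
    if mode not in ("truncated", "full"):
        raise ValueError(f"mode must be 'truncated' or 'full', got {mode!r}")
    n, m = region.n, region.m
    z = region.z
    w, v = np.linalg.eigh(region.ld.r)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    keep = w > min_eigval
    if mode == "truncated":
        keep &= np.arange(m) < min(max_eig, m)
    q = int(keep.sum())
    if q == 0:
        raise ValueError("no eigenvalue above min_eigval; cannot estimate")
    proj = v[:, keep].T @ z
    quad = float(np.sum(proj**2 / w[keep]))
    h2 = (quad - q) / (n - q)
    h2c = min(max(h2, 0.0), 1.0)  # SE evaluated at clipped point estimate
    var = (n / (n - q)) ** 2 * (2 * q * (1 - h2c) ** 2 / n**2
                                + 4 * h2c * (1 - h2c) / n)
    return QuadFormResult(h2=float(h2), q_used=q, se=float(math.sqrt(max(var, 0.0))),
                          mode=mode)


def stepwise_conditional(region: RegionSummary, p_threshold: float = 5e-8,
                         max_steps: int = 10) -> list:
    """Approximate stepwise conditional selection from summary statistics.

    At each step the candidate with the largest conditional |z| given the
    selected set S is added. The conditional z is the joint-regression
    t-ratio reconstructed from summary data: with u = D^{1/2} z (so that
    u = sqrt(n) b_marginal) and a = R_jS R_SS^-1,

        z_cond = (u_j - a u_S) / sqrt(sigma2_T * (1 - a R_Sj)),

    where sigma2_T is the ML residual variance of the joint model on
    S + {j}. For small effects this reduces to the familiar
    (z_j - R_jS R_SS^-1 z_S)/sqrt(1 - R_jS R_SS^-1 R_Sj) form. Stops when
    no candidate reaches ``p_threshold`` or after ``max_steps``; candidates
    with residual LD variance <= 1e-6 are skipped as collinear.

    Returns a list of (index, marginal_z, conditional_z) in selection order.
    """
    z_threshold = stats.norm.isf(p_threshold / 2.0)
    z = region.z
    n = region.n
    u = z / np.sqrt(1.0 + z**2 / n)  # D^{1/2} z
    r = region.ld.r
    m = region.m
    selected: list = []
    out = []
    for _ in range(max_steps):
        if selected:
            rs_inv = np.linalg.inv(r[np.ix_(selected, selected)])
            us = u[selected]
            base_quad = float(us @ rs_inv @ us)
        best_j, best_zc = None, 0.0
        for j in range(m):
            if j in selected:
                continue
            if selected:
                rj = r[j, selected]
                a = rj @ rs_inv
                denom = 1.0 - float(a @ rj)
                if denom <= 1e-6:
                    continue
                num = float(u[j] - a @ us)
                quad_t = base_quad + num**2 / denom
            else:
                num, denom, quad_t = float(u[j]), 1.0, u[j] ** 2
            sigma2_t = max(1.0 - quad_t / n, 1e-8)
            zc = num / math.sqrt(sigma2_t * denom)
            if abs(zc) > abs(best_zc):
                best_j, best_zc = j, zc
        if best_j is None or abs(best_zc) < z_threshold:
            break
        selected.append(best_j)
        out.append((best_j, float(z[best_j]), float(best_zc)))
    return out


def lead_variant_h2(region: RegionSummary, draws: int = 10_000, seed: int = 0,
                    prior_sd: float = 0.05,
                    large_effect_threshold: float = 0.01) -> RegionResult:
    """Heritability captured assuming a single causal variant (K = 1)."""
    return fine_map_region(
        region, max_causal=1, draws=draws, seed=seed, prior_sd=prior_sd,
        large_effect_threshold=large_effect_threshold, exact=True,
        compute_summaries=False,
    )


@dataclass(frozen=True)
class ClumpedRegion:
    chromosome: str
    start: int
    end: int
    lead_index: int
    lead_pvalue: float


def clump_regions(positions, pvalues, window_bp: int = 1_000_000,
                  threshold: float = 5e-8, chromosomes=None) -> list:
    """Merge +/- window intervals around significant variants per chromosome.

    Each merged region carries the index of its minimum-P (lead) variant.
    """
    positions = np.asarray(positions, dtype=int)
    pvalues = np.asarray(pvalues, dtype=float)
    if chromosomes is None:
        chromosomes = np.full(positions.shape, "1", dtype=object)
    else:
        chromosomes = np.asarray(chromosomes, dtype=object)
    sig = np.flatnonzero(pvalues < threshold)
    out = []
    for chrom in sorted(set(chromosomes[sig])):
        hits = sig[chromosomes[sig] == chrom]
        hits = hits[np.argsort(positions[hits])]
        current = None
        members: list = []
        for j in hits:
            lo, hi = positions[j] - window_bp, positions[j] + window_bp
            if current is None or lo > current[1]:
                if current is not None:
                    lead = min(members, key=lambda i: (pvalues[i], i))
                    out.append(ClumpedRegion(str(chrom), current[0], current[1],
                                             int(lead), float(pvalues[lead])))
                current = [lo, hi]
                members = [j]
            else:
                current[1] = max(current[1], hi)
                members.append(j)
        if current is not None:
            lead = min(members, key=lambda i: (pvalues[i], i))
            out.append(ClumpedRegion(str(chrom), current[0], current[1],
                                     int(lead), float(pvalues[lead])))
    return out


def in_hla(chromosome: str, position: int) -> bool:
    """True when the coordinate falls in the extended HLA interval (GRCh37)."""
    chrom, lo, hi = HLA_REGION
    return str(chromosome).lstrip("chr") == chrom and lo <= position <= hi
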