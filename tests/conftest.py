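import numpy as np
import pytest

from regfine.summary_data import LDMatrix, RegionSummary, Variant


def region_from_z(z, ld, n, mafs=None):
    """Build a RegionSummary directly from z-scores and an LD matrix.

    beta/se are back-computed under the ML convention se = sqrt(1/(n+z^2)),
    so the region's z property reproduces the input exactly.
    """
    z = np.asarray(z, dtype=float)
    m = z.size
    if mafs is None:
        mafs = np.full(m, 0.25)
    se = np.sqrt(1.0 / (n + z**2))
    beta = z * se
    variants = tuple(
        Variant(id=f"rs{j + 1}", chromosome="1", position=(j + 1) * 1000,
                allele1="A", allele2="G", maf=float(mafs[j]),
                beta=float(beta[j]), se=float(se[j]))
        for j in range(m)
    )
    return RegionSummary(variants=variants, ld=LDMatrix(np.asarray(ld, dtype=float)),
                         n=n)


def standardize(x):
    """Center and scale to unit variance in the 1/n convention."""
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    return x / np.sqrt((x**2).mean())


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def identity_region():
    """Five independent variants, one strong signal."""
    return region_from_z([1.0, 8.0, -0.5, 2.0, 0.0], np.eye(5), 20_000)
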