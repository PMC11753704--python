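"""Domain types and IO for region-level GWAS summary statistics.

A fine-mapped region is described by per-variant univariate association
summaries (effect estimate and standard error on the standardized scale,
equivalently a z-score), the matrix of pairwise genotype correlations
(LD) in the same variant order, and the GWAS sample size n.

File dialect follows the space-delimited conventions of the wider
fine-mapping ecosystem: a "z" file with the header
``rsid chromosome position allele1 allele2 maf beta se`` and a plain
whitespace-delimited square LD matrix.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "Variant",
    "LDMatrix",
    "RegionSummary",
    "GenotypeMatrix",
    "InputError",
    "ValidationError",
    "read_region",
    "write_region",
    "ld_from_genotypes",
    "summary_from_individual",
    "flip_alleles",
]

Z_COLUMNS = ["rsid", "chromosome", "position", "allele1", "allele2", "maf", "beta", "se"]


class InputError(ValueError):
    """Malformed or inconsistent input files."""


class ValidationError(ValueError):
    """A domain invariant is violated."""


@dataclass(frozen=True)
class Variant:
    """One biallelic variant with its univariate association summary.

    ``beta`` and ``se`` are the slope and standard error of the univariate
    regression of the standardized phenotype on the standardized genotype,
    so ``z = beta / se`` is the usual GWAS z-score.
    """

    id: str
    chromosome: str
    position: int
    allele1: str
    allele2: str
    maf: float
    beta: float
    se: float

    def __post_init__(self) -> None:
        if not (self.se > 0):
            raise ValidationError(f"variant {self.id}: se must be > 0, got {self.se}")
        if not (0 < self.maf <= 0.5):
            raise ValidationError(f"variant {self.id}: maf must be in (0, 0.5], got {self.maf}")
        if not np.isfinite(self.beta / self.se):
            raise ValidationError(f"variant {self.id}: z = beta/se is not finite")

    @property
    def z(self) -> float:
        return self.beta / self.se


@dataclass(frozen=True)
class LDMatrix:
    """Symmetric matrix of pairwise sample correlations between variants."""

    r: np.ndarray

    _SYM_TOL = 1e-10
    _OFFDIAG_TOL = 1e-8
    _EIG_TOL = -1e-6

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        object.__setattr__(self, "r", r)
        if r.ndim != 2 or r.shape[0] != r.shape[1]:
            raise ValidationError(f"LD matrix must be square, got shape {r.shape}")
        if not np.allclose(r, r.T, atol=self._SYM_TOL, rtol=0):
            raise ValidationError("LD matrix is not symmetric to 1e-10")
        if not np.all(np.diag(r) == 1.0):
            raise ValidationError("LD matrix diagonal entries must be exactly 1")
        if np.any(np.abs(r) > 1 + self._OFFDIAG_TOL):
            raise ValidationError("LD matrix has |r| > 1 beyond tolerance")
        if r.shape[0] > 1:
            w = np.linalg.eigvalsh(0.5 * (r + r.T))
            if w[0] < self._EIG_TOL:
                raise ValidationError(f"LD matrix is not near-PSD (min eigenvalue {w[0]:.3g})")

    @property
    def m(self) -> int:
        return self.r.shape[0]

    def submatrix(self, indices) -> np.ndarray:
        idx = np.asarray(indices, dtype=int)
        return self.r[np.ix_(idx, idx)]


@dataclass(frozen=True)
class RegionSummary:
    """Summary data for one genomic region: variants, LD and sample size."""

    variants: tuple
    ld: LDMatrix
    n: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "variants", tuple(self.variants))
        if len(self.variants) < 1:
            raise ValidationError("region must contain at least one variant")
        if self.ld.m != len(self.variants):
            raise InputError(
                f"LD matrix dimension {self.ld.m} does not match "
                f"{len(self.variants)} variants"
            )
        if not (int(self.n) > 0 and int(self.n) == self.n):
            raise ValidationError(f"sample size must be a positive integer, got {self.n}")
        object.__setattr__(self, "n", int(self.n))

    @property
    def m(self) -> int:
        return len(self.variants)

    @property
    def z(self) -> np.ndarray:
        """Vector of z-scores beta/se in variant order."""
        return np.array([v.z for v in self.variants])

    @property
    def rsids(self) -> list:
        return [v.id for v in self.variants]


@dataclass(frozen=True)
class GenotypeMatrix:
    """n x m matrix of column-standardized genotype dosages.

    Standardization uses the 1/n (maximum-likelihood) variance convention so
    that ``g.T @ g / n`` has unit diagonal exactly.
    """

    g: np.ndarray

    def __post_init__(self) -> None:
        g = np.asarray(self.g, dtype=float)
        object.__setattr__(self, "g", g)
        if g.ndim != 2:
            raise ValidationError("genotype matrix must be 2-dimensional")
        means = g.mean(axis=0)
        if np.any(np.abs(means) > 1e-8):
            raise ValidationError("genotype columns must have mean 0 (|mean| <= 1e-8)")
        var = (g**2).mean(axis=0)
        if np.any(np.abs(var - 1) > 1e-6):
            raise ValidationError("genotype columns must have variance 1 (within 1e-6)")

    @property
    def n(self) -> int:
        return self.g.shape[0]

    @property
    def m(self) -> int:
        return self.g.shape[1]

    @classmethod
    def from_raw(cls, raw: np.ndarray) -> "GenotypeMatrix":
        """Center and scale raw dosages column-wise (1/n variance convention)."""
        raw = np.asarray(raw, dtype=float)
        centered = raw - raw.mean(axis=0)
        sd = np.sqrt((centered**2).mean(axis=0))
        zero = np.flatnonzero(sd == 0)
        if zero.size:
            raise InputError(f"constant genotype column(s): {zero.tolist()}")
        return cls(centered / sd)


def read_region(z_path, ld_path, n: int) -> RegionSummary:
    """Read a region from a z file and an LD matrix file.

    The z file is whitespace-delimited with header
    ``rsid chromosome position allele1 allele2 maf beta se``; the LD file is
    a whitespace-delimited m x m matrix in the same variant order. Allele
    alignment between the two files is the caller's responsibility.
    """
    try:
        df = pd.read_csv(z_path, sep=r"\s+", dtype={"rsid": str, "chromosome": str},
                         float_precision="round_trip")
    except Exception as exc:  # noqa: BLE001 - surface as our input error
        raise InputError(f"cannot parse z file {z_path}: {exc}") from exc
    missing = [c for c in Z_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"z file {z_path} is missing columns {missing}")

    variants = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        try:
            variants.append(
                Variant(
                    id=str(row.rsid),
                    chromosome=str(row.chromosome),
                    position=int(row.position),
                    allele1=str(row.allele1),
                    allele2=str(row.allele2),
                    maf=float(row.maf),
                    beta=float(row.beta),
                    se=float(row.se),
                )
            )
        except (TypeError, ValueError) as exc:
            raise InputError(f"z file {z_path}, line {i}: {exc}") from exc

    ld_raw = np.loadtxt(ld_path, ndmin=2)
    if ld_raw.shape != (len(variants), len(variants)):
        raise InputError(
            f"LD file {ld_path} has shape {ld_raw.shape}, expected "
            f"({len(variants)}, {len(variants)})"
        )
    return RegionSummary(variants=tuple(variants), ld=LDMatrix(ld_raw), n=n)


def write_region(region: RegionSummary, z_path, ld_path) -> None:
    """Write a region back to z/LD files (lossless round-trip with read_region)."""
    rows = [
        (v.id, v.chromosome, v.position, v.allele1, v.allele2,
         repr(v.maf), repr(v.beta), repr(v.se))
        for v in region.variants
    ]
    df = pd.DataFrame(rows, columns=Z_COLUMNS)
    buf = io.StringIO()
    df.to_csv(buf, sep=" ", index=False)
    with open(z_path, "w") as fh:
        fh.write(buf.getvalue())
    np.savetxt(ld_path, region.ld.r, fmt="%.17g")


def ld_from_genotypes(g: GenotypeMatrix) -> LDMatrix:
    """Sample correlation matrix g'g/n of standardized genotype columns."""
    if g.n < 2:
        raise InputError("need at least two individuals to compute LD")
    r = g.g.T @ g.g / g.n
    r = 0.5 * (r + r.T)
    np.fill_diagonal(r, 1.0)
    np.clip(r, -1.0, 1.0, out=r)
    return LDMatrix(r)


def summary_from_individual(g: GenotypeMatrix, y: np.ndarray,
                            variants=None) -> RegionSummary:
    """Per-variant univariate regression summaries from individual-level data.

    ``y`` must be standardized (mean 0, variance 1 in the 1/n convention).
    For each column the slope is b = g_l'y/n and the standard error uses the
    maximum-likelihood residual variance, se = sqrt(mean((y - b g_l)^2) / n).
    With these conventions z = b/se satisfies the exact summary-data
    identities used by the configuration Bayes factor.
    """
    y = np.asarray(y, dtype=float)
    if y.shape[0] != g.n:
        raise InputError(f"phenotype length {y.shape[0]} != genotype rows {g.n}")
    n = g.n
    b = g.g.T @ y / n
    # mean residual sum of squares per column, vectorized
    yty = float(y @ y) / n
    sigma2 = yty - b**2  # since columns have unit 1/n-variance
    sigma2 = np.maximum(sigma2, 1e-300)
    se = np.sqrt(sigma2 / n)

    if variants is None:
        variants = [
            Variant(id=f"v{j}", chromosome="1", position=j + 1, allele1="A",
                    allele2="G", maf=0.25, beta=float(b[j]), se=float(se[j]))
            for j in range(g.m)
        ]
    else:
        variants = [replace(v, beta=float(b[j]), se=float(se[j]))
                    for j, v in enumerate(variants)]
    return RegionSummary(variants=tuple(variants), ld=ld_from_genotypes(g), n=n)


def flip_alleles(region: RegionSummary, indices) -> RegionSummary:
    """Recode the listed variants to the opposite allele.

    Swaps allele labels, negates beta, and negates the corresponding LD
    rows/columns off the diagonal. The minor allele frequency is unchanged
    (it refers to the minor allele, not a particular coding).
    """
    idx = set(int(i) for i in np.atleast_1d(indices))
    variants = []
    for j, v in enumerate(region.variants):
        if j in idx:
            variants.append(replace(v, allele1=v.allele2, allele2=v.allele1,
                                    beta=-v.beta))
        else:
            variants.append(v)
    sign = np.ones(region.m)
    sign[list(idx)] = -1
    r = region.ld.r * np.outer(sign, sign)
    np.fill_diagonal(r, 1.0)
    return RegionSummary(variants=tuple(variants), ld=LDMatrix(r), n=region.n)
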