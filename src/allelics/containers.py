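"""Core in-memory containers shared across the analysis modules.

The central object is :class:`GenotypeMatrix`: additively coded genotypes
(count of the alternate allele, 0/1/2, ``NaN`` for missing) for a set of
samples over a set of variants, with per-variant metadata (position, alleles,
minor-allele frequency and, when the data come from imputation, an INFO
quality score in [0, 1]).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

VARIANT_COLUMNS = ["id", "chrom", "pos", "ref", "alt", "maf", "info"]


class MonomorphicError(ValueError):
    """Raised when a test is requested for a variant with no variation."""


class DegeneratePhenotypeError(ValueError):
    """Raised when the phenotype has a single class."""


def make_variant_table(
    ids: Sequence[str],
    chrom: str | Sequence[str] = "5",
    pos: Optional[Sequence[int]] = None,
    ref: str | Sequence[str] = "G",
    alt: str | Sequence[str] = "C",
    maf: Optional[Sequence[float]] = None,
    info: Optional[Sequence[float]] = None,
) -> pd.DataFrame:
    """Assemble a variant-metadata table with the standard columns."""
    m = len(ids)
    if pos is None:
        # default: evenly spaced 1-based positions inside chr5p15.33 Region 2
        pos = [1_306_281 + 1000 * i for i in range(m)]
    tbl = pd.DataFrame(
        {
            "id": list(ids),
            "chrom": [chrom] * m if isinstance(chrom, str) else list(chrom),
            "pos": np.asarray(pos, dtype=np.int64),
            "ref": [ref] * m if isinstance(ref, str) else list(ref),
            "alt": [alt] * m if isinstance(alt, str) else list(alt),
            "maf": np.full(m, np.nan) if maf is None else np.asarray(maf, float),
            "info": np.full(m, np.nan) if info is None else np.asarray(info, float),
        }
    )
    return tbl


@dataclass
class GenotypeMatrix:
    """Samples x variants additive genotypes with variant metadata.

    Parameters
    ----------
    sample_ids:
        Sample identifiers, one per row of ``genotypes``.
    variants:
        DataFrame with columns ``id, chrom, pos, ref, alt, maf, info``.
        ``info`` may be NaN (absent; treated as passing QC).
    genotypes:
        float array of shape (n_samples, n_variants); entries in {0, 1, 2}
        or NaN for missing.
    """

    sample_ids: list[str]
    variants: pd.DataFrame
    genotypes: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=float)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be 2-D (samples x variants)")
        n, m = self.genotypes.shape
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match genotype rows")
        if len(self.variants) != m:
            raise ValueError("variant table length does not match genotype columns")
        missing_cols = set(VARIANT_COLUMNS) - set(self.variants.columns)
        if missing_cols:
            raise ValueError(f"variant table missing columns: {sorted(missing_cols)}")
        vals = self.genotypes[~np.isnan(self.genotypes)]
        if vals.size and not np.isin(vals, [0.0, 1.0, 2.0]).all():
            raise ValueError("genotype values must be 0, 1, 2 or missing")
        maf = self.variants["maf"].to_numpy(float)
        ok = np.isnan(maf) | ((maf >= 0) & (maf <= 0.5))
        if not ok.all():
            raise ValueError("MAF must lie in [0, 0.5]")
        info = self.variants["info"].to_numpy(float)
        ok = np.isnan(info) | ((info >= 0) & (info <= 1))
        if not ok.all():
            raise ValueError("INFO must lie in [0, 1] when present")
        for _, grp in self.variants.groupby("chrom", sort=False):
            p = grp["pos"].to_numpy()
            if not (np.diff(p) > 0).all():
                raise ValueError("positions must be strictly increasing within a chromosome")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.genotypes.shape[1]

    @property
    def variant_ids(self) -> list[str]:
        return self.variants["id"].tolist()

    def index_of(self, variant_id: str) -> int:
        idx = self.variants.index[self.variants["id"] == variant_id]
        if len(idx) == 0:
            raise KeyError(f"variant {variant_id!r} not found")
        return int(idx[0])

    def column(self, variant_id: str) -> np.ndarray:
        """Genotype dosages for one variant (copy)."""
        return self.genotypes[:, self.index_of(variant_id)].copy()

    def observed_maf(self) -> np.ndarray:
        """Per-variant sample minor-allele frequency (ignoring missing)."""
        with np.errstate(invalid="ignore"):
            p = np.nanmean(self.genotypes, axis=0) / 2.0
        return np.minimum(p, 1.0 - p)

    def subset_samples(self, rows: np.ndarray) -> "GenotypeMatrix":
        rows = np.asarray(rows)
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in rows],
            variants=self.variants.copy(),
            genotypes=self.genotypes[rows, :].copy(),
        )


@dataclass(frozen=True)
class AssociationResult:
    """One variant's association test under an optional conditioning set."""

    variant_id: str
    beta: float
    se: float
    score_stat: float
    p_value: float
    n: int
    conditioned_on: tuple[str, ...] = ()
    beta_reliable: bool = True

    def __post_init__(self) -> None:
        if self.variant_id in self.conditioned_on:
            raise ValueError("conditioning set must not contain the tested variant")
        if not np.isnan(self.p_value) and not (0 < self.p_value <= 1):
            raise ValueError("p-value must lie in (0, 1]")
        if not np.isnan(self.score_stat) and self.score_stat < 0:
            raise ValueError("score statistic must be non-negative")


@dataclass(frozen=True)
class LdPair:
    """Linkage disequilibrium between two loci.

    ``hap_freqs`` are the two-locus haplotype frequencies (pAB, pAb, paB, pab)
    where A/B denote the alternate alleles at the two loci; ``phased`` records
    whether they were counted from haplotypes or EM-estimated from genotypes.
    """

    variant_i: str
    variant_j: str
    r2: float
    d_prime: float
    hap_freqs: tuple[float, float, float, float]
    phased: bool

    def __post_init__(self) -> None:
        if not (-1e-9 <= self.r2 <= 1 + 1e-9):
            raise ValueError("r2 must lie in [0, 1]")
        if not (-1e-9 <= self.d_prime <= 1 + 1e-9):
            raise ValueError("D' must lie in [0, 1]")
        if self.r2 > self.d_prime + 1e-9:
            raise ValueError("r2 cannot exceed D'")
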