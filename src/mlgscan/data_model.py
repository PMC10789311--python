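"""Core containers for phased haplotypes and unphased multi-locus genotypes.

A *multi-locus genotype* (MLG) is the per-individual sequence of derived-allele
counts across sites: at each biallelic site a diploid individual carries 0, 1 or
2 copies of the derived allele.  Collapsing a phased haplotype pair into these
counts erases phase but preserves everything the unphased homozygosity
statistics need.

Matrices are stored sites x samples (``HaplotypeMatrix``: one column per
haplotype, alleles in {0,1}; ``GenotypeMatrix``: one column per diploid
individual, entries in {0,1,2}).  Site metadata lives in a plain pandas
DataFrame ("site table") with columns ``locus_id``, ``chrom``, ``pos_bp``,
optional ``pos_cm`` and, once a matrix is attached, ``freq_derived``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

SITE_TABLE_COLUMNS = ("locus_id", "chrom", "pos_bp")


@dataclass
class HaplotypeMatrix:
    """Phased alleles, shape (n_sites, n_haplotypes); consecutive column pairs
    (2i, 2i+1) are the two haplotypes of diploid individual i."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.ascontiguousarray(self.values, dtype=np.int8)
        if self.values.ndim != 2:
            raise ValueError("haplotype matrix must be 2-D (sites x haplotypes)")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("haplotype entries must be 0 (ancestral) or 1 (derived)")

    @property
    def n_sites(self) -> int:
        return self.values.shape[0]

    @property
    def n_haplotypes(self) -> int:
        return self.values.shape[1]


@dataclass
class GenotypeMatrix:
    """Unphased derived-allele counts, shape (n_sites, n_individuals)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.ascontiguousarray(self.values, dtype=np.int8)
        if self.values.ndim != 2:
            raise ValueError("genotype matrix must be 2-D (sites x individuals)")
        if not np.isin(self.values, (0, 1, 2)).all():
            raise ValueError("genotype entries must be derived-allele counts in {0,1,2}")
        if self.values.shape[1] < 2:
            raise ValueError("need at least 2 individuals")

    @property
    def n_sites(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        return self.values.shape[1]


def make_site_table(
    pos_bp,
    locus_id=None,
    chrom: str = "1",
    pos_cm=None,
) -> pd.DataFrame:
    """Build a validated site table.  ``pos_bp`` is 1-based and must be
    strictly increasing within the (single) chromosome."""
    pos_bp = np.asarray(pos_bp, dtype=np.int64)
    if pos_bp.ndim != 1:
        raise ValueError("pos_bp must be 1-D")
    if len(pos_bp) > 1 and not (np.diff(pos_bp) > 0).all():
        raise ValueError("pos_bp must be strictly increasing")
    if locus_id is None:
        locus_id = [f"{chrom}:{p}" for p in pos_bp]
    table = pd.DataFrame({"locus_id": list(locus_id), "chrom": chrom, "pos_bp": pos_bp})
    if pos_cm is not None:
        table["pos_cm"] = np.asarray(pos_cm, dtype=float)
    return table


def validate_site_table(sites: pd.DataFrame, n_sites: int | None = None) -> None:
    for col in SITE_TABLE_COLUMNS:
        if col not in sites.columns:
            raise ValueError(f"site table missing column {col!r}")
    if n_sites is not None and len(sites) != n_sites:
        raise ValueError(f"site table has {len(sites)} rows, matrix has {n_sites} sites")
    pos = sites["pos_bp"].to_numpy()
    if len(pos) > 1 and not (np.diff(pos) > 0).all():
        raise ValueError("pos_bp must be strictly increasing")


def collapse_to_genotypes(haps: HaplotypeMatrix) -> GenotypeMatrix:
    """Collapse phased haplotypes to unphased multi-locus genotypes.

    Each individual's entry is the number of derived alleles across its two
    haplotypes; (0,0) -> 0, (0,1)/(1,0) -> 1, (1,1) -> 2.
    """
    if haps.n_haplotypes % 2 != 0:
        raise ValueError(
            f"odd haplotype count ({haps.n_haplotypes}): haplotypes must form diploid pairs"
        )
    v = haps.values
    return GenotypeMatrix(v[:, 0::2] + v[:, 1::2])


def derived_allele_frequency(genotypes: GenotypeMatrix, site: int) -> float:
    """Diploid derived-allele frequency at one site: (sum of counts) / 2n."""
    if genotypes.n_sites == 0:
        raise ValueError("empty genotype matrix")
    col = genotypes.values[site]
    return float(col.sum(dtype=np.int64)) / (2 * genotypes.n)


def all_frequencies(genotypes: GenotypeMatrix) -> np.ndarray:
    return genotypes.values.sum(axis=1, dtype=np.int64) / (2.0 * genotypes.n)


def attach_frequencies(sites: pd.DataFrame, genotypes: GenotypeMatrix) -> pd.DataFrame:
    """Return a copy of ``sites`` with a ``freq_derived`` column computed from
    the matrix."""
    validate_site_table(sites, genotypes.n_sites)
    out = sites.copy()
    out["freq_derived"] = all_frequencies(genotypes)
    return out


def filter_core_sites(
    genotypes: GenotypeMatrix, sites: pd.DataFrame, maf_threshold: float
) -> np.ndarray:
    """Boolean mask of sites usable as scan cores: minor-allele frequency at
    least ``maf_threshold``.  Masked-out sites still extend haplotypes; they
    are only excluded as cores."""
    if not 0.0 <= maf_threshold <= 0.5:
        raise ValueError("maf_threshold must be in [0, 0.5]")
    validate_site_table(sites, genotypes.n_sites)
    freq = all_frequencies(genotypes)
    maf = np.minimum(freq, 1.0 - freq)
    return maf >= maf_threshold
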