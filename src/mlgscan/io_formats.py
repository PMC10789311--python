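"""File formats: VCF input, PLINK-style map files, tab-separated score files.

Coordinates are 1-based bp throughout (VCF convention).  Score files carry
one statistic each, named ``<prefix>.<stat>[.unphased].out`` with a
``.norm`` suffix appended after standardization; floats are written with six
significant digits so that written files round-trip exactly.
"""

from __future__ import annotations

import gzip
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import (
    GenotypeMatrix,
    HaplotypeMatrix,
    attach_frequencies,
    collapse_to_genotypes,
    make_site_table,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_vcf",
    "write_vcf",
    "read_map",
    "write_map",
    "write_scores",
    "read_scores",
    "score_filename",
]

SCORE_FLOAT_FORMAT = "%.6g"


def read_vcf(path, unphased: bool = False):
    """Read biallelic diploid SNVs from a VCF.

    In phased mode every GT must use the ``|`` separator and a
    HaplotypeMatrix is returned; in unphased mode ``/`` or ``|`` are accepted
    and derived-allele counts are returned as a GenotypeMatrix.  The ALT
    allele is treated as derived.  Multi-allelic records and records with
    missing calls are skipped (logged).  Returns (matrix, site table with
    freq_derived).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    if len(vcf.samples) == 0:
        raise ValueError(f"{path}: VCF contains no samples")

    rows = []
    pos = []
    ids = []
    chroms = set()
    n_multi = n_missing = 0
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_multi += 1
            continue
        gts = var.genotypes  # [[a, b, phased], ...]
        row = np.empty((len(gts), 2), dtype=np.int8)
        ok = True
        for i, gt in enumerate(gts):
            if len(gt) < 3 or gt[0] < 0 or gt[1] < 0:
                ok = False
                break
            if not unphased and not gt[2]:
                raise ValueError(
                    f"{path}: unphased genotype at {var.CHROM}:{var.POS} "
                    "(use unphased mode or phase the data)"
                )
            row[i, 0], row[i, 1] = gt[0], gt[1]
        if not ok:
            n_missing += 1
            continue
        chroms.add(var.CHROM)
        pos.append(var.POS)
        ids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}")
        rows.append(row)
    if n_multi or n_missing:
        logger.info(
            "%s: skipped %d non-biallelic-SNV and %d incomplete records",
            path, n_multi, n_missing,
        )
    if len(chroms) > 1:
        raise ValueError(f"{path}: expected a single chromosome, found {sorted(chroms)}")
    if not rows:
        raise ValueError(f"{path}: no usable biallelic records")

    stacked = np.stack(rows)  # (sites, individuals, 2)
    chrom = next(iter(chroms))
    sites = make_site_table(np.asarray(pos, dtype=np.int64), locus_id=ids, chrom=chrom)
    if unphased:
        gm = GenotypeMatrix(stacked.sum(axis=2, dtype=np.int8))
        return gm, attach_frequencies(sites, gm)
    hm = HaplotypeMatrix(stacked.reshape(stacked.shape[0], -1))
    return hm, attach_frequencies(sites, collapse_to_genotypes(hm))


def write_vcf(haps: HaplotypeMatrix, sites: pd.DataFrame, path, chrom=None) -> None:
    """Write phased haplotypes as a minimal VCF (GT-only, '|' separated)."""
    if haps.n_haplotypes % 2 != 0:
        raise ValueError("haplotypes must form diploid pairs")
    n_ind = haps.n_haplotypes // 2
    samples = [f"ind{i}" for i in range(n_ind)]
    chrom = chrom if chrom is not None else str(sites["chrom"].iloc[0])
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        values = haps.values
        for row, (_, site) in zip(values, sites.iterrows()):
            gts = "\t".join(
                f"{row[2 * i]}|{row[2 * i + 1]}" for i in range(n_ind)
            )
            fh.write(
                f"{chrom}\t{site.pos_bp}\t{site.locus_id}\tA\tT\t.\tPASS\t.\tGT\t{gts}\n"
            )


def write_map(sites: pd.DataFrame, path, cm_per_mb: float = 1.0) -> None:
    """Write a 4-column PLINK-style map (chrom, locus_id, cM, bp).  Without a
    pos_cm column, genetic positions use a uniform cm_per_mb rate."""
    if "pos_cm" in sites.columns:
        cm = sites["pos_cm"].to_numpy(float)
    else:
        cm = sites["pos_bp"].to_numpy(float) * cm_per_mb / 1e6
    with open(path, "w") as fh:
        for (_, site), c in zip(sites.iterrows(), cm):
            fh.write(f"{site.chrom}\t{site.locus_id}\t{c:.8g}\t{site.pos_bp}\n")


def read_map(path, sites: pd.DataFrame) -> pd.DataFrame:
    """Attach genetic positions (cM) from a whitespace-delimited map file
    (chrom, locus_id, cM, bp) to a site table, matching on bp position.
    Every site must be present in the map; extra map rows are ignored."""
    m = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        names=["chrom", "locus_id", "pos_cm", "pos_bp"],
        dtype={"chrom": str, "locus_id": str, "pos_cm": float, "pos_bp": np.int64},
    )
    if len(m) > 1 and not (np.diff(m["pos_cm"].to_numpy()) > 0).all():
        raise ValueError(f"{path}: cM positions must be strictly increasing")
    lookup = dict(zip(m["pos_bp"], m["pos_cm"]))
    missing = [p for p in sites["pos_bp"] if p not in lookup]
    if missing:
        raise ValueError(
            f"{path}: {len(missing)} site(s) absent from map, first at bp {missing[0]}"
        )
    out = sites.copy()
    out["pos_cm"] = [lookup[p] for p in sites["pos_bp"]]
    return out


def score_filename(prefix: str, statistic: str, unphased: bool, norm: bool = False) -> str:
    name = f"{prefix}.{statistic}"
    if unphased:
        name += ".unphased"
    name += ".out"
    if norm:
        name += ".norm"
    return name


def _open_text(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def write_scores(df: pd.DataFrame, path) -> None:
    """Write a score frame as a tab-separated file with a header; floats at
    six significant digits."""
    df.to_csv(path, sep="\t", index=False, float_format=SCORE_FLOAT_FORMAT)


def read_scores(path) -> pd.DataFrame:
    """Read a score file back; raises with the offending line number on
    malformed rows."""
    try:
        df = pd.read_csv(_open_text(path), sep="\t")
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed score file: {exc}") from exc
    required = {"locus_id", "pos_bp", "freq_derived", "ihh_num", "ihh_den", "score"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    numeric = [c for c in df.columns if c != "locus_id"]
    for col in numeric:
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna() & (df[col].astype(str).str.lower() != "nan")
        if bad.any():
            line = int(np.nonzero(bad.to_numpy())[0][0]) + 2  # +1 header, +1 1-based
        else:
            line = None
        if line is not None:
            raise ValueError(f"{path}: malformed value in column {col!r} at line {line}")
        df[col] = parsed
    df["pos_bp"] = df["pos_bp"].astype(np.int64)
    return df
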