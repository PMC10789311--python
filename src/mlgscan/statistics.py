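"""Per-site haplotype-homozygosity selection statistics.

Unphased statistics operate on multi-locus genotypes (derived-allele counts
0/1/2 per individual); phased baselines operate on haplotype alleles.

iHS / nSL (single population): for each core site, integrate the decay of
EHH_c and cEHH_c for the homozygous ancestral (c=0) and homozygous derived
(c=2) core classes, form

    iHS_2 = log10(iHH_2 / ciHH_2)      iHS_0 = log10(iHH_0 / ciHH_0)

and report iHS_2 when iHS_2 > iHS_0, else -iHS_0.  Positive scores flag long
low-diversity sequences around a homozygous *derived* core, negative around a
homozygous *ancestral* core.  nSL is the same computation with distance
measured in sites instead of basepairs/centimorgans.

XP-EHH / XP-nSL (two populations): full-sample iHH in each population,
XP = log10(iHH_A / iHH_B), positive when population A carries the longer
high-frequency haplotypes.

iHS/nSL are later standardized within 1% derived-allele-frequency bins and XP
statistics genome-wide (see :mod:`mlgscan.normalization`).
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import _kernels
from .data_model import (
    GenotypeMatrix,
    HaplotypeMatrix,
    collapse_to_genotypes,
    filter_core_sites,
    validate_site_table,
)
from .ehh import (
    ExtensionPolicy,
    _distance_coordinate,
    _step_distances,
    _trapezoid,
    walk_trajectory,
)

logger = logging.getLogger(__name__)

STATISTICS = ("ihs", "nsl", "xpehh", "xpnsl")
SITE_DISTANCE_STATS = ("nsl", "xpnsl")
XP_STATS = ("xpehh", "xpnsl")

SCORE_COLUMNS = ["locus_id", "pos_bp", "freq_derived", "ihh_num", "ihh_den", "score"]

# kernel quantity indices: EHH_c at 1+2c, cEHH_c at 2+2c (0 = full sample)
_UNPHASED_WATCH = (1, 2, 5, 6)
_PHASED_WATCH = (1, 3)
_FULL_WATCH = (0,)


@dataclass
class ScanConfig:
    """Configuration of one scan run."""

    statistic: str
    unphased: bool = True
    distance_mode: Optional[str] = None  # default: sites for nSL/XP-nSL, bp otherwise
    policy: ExtensionPolicy = field(default_factory=ExtensionPolicy)
    maf_threshold: float = 0.05

    def __post_init__(self) -> None:
        if self.statistic not in STATISTICS:
            raise ValueError(f"unknown statistic {self.statistic!r}")
        if self.distance_mode is None:
            self.distance_mode = (
                "sites" if self.statistic in SITE_DISTANCE_STATS else "bp"
            )
        site_stat = self.statistic in SITE_DISTANCE_STATS
        if site_stat != (self.distance_mode == "sites"):
            raise ValueError(
                f"distance_mode {self.distance_mode!r} is incompatible with "
                f"statistic {self.statistic!r}"
            )

    @property
    def label(self) -> str:
        return self.statistic + (".unphased" if self.unphased else "")


@dataclass
class ScoreRecord:
    locus_id: str
    pos_bp: int
    freq_derived: float
    ihh_num: float
    ihh_den: float
    score: float
    statistic: str


def combine_unphased_ihs(
    ihh2: float, cihh2: float, ihh0: float, cihh0: float
) -> tuple[float, float, float]:
    """Apply the two-branch unphased iHS rule.

    Returns (score, selected iHH numerator, selected iHH denominator).  Ties
    fall through to the ancestral branch (-iHS_0), following the two-branch
    rule literally.
    """
    # difference of logs keeps sign symmetries exact in floating point
    ihs2 = math.log10(ihh2) - math.log10(cihh2)
    ihs0 = math.log10(ihh0) - math.log10(cihh0)
    if ihs2 > ihs0:
        return ihs2, ihh2, cihh2
    return -ihs0, ihh0, cihh0


def _branch_length(q: np.ndarray, npts: int, idx_pair, cutoff: float):
    """Number of points a branch keeps: up to and including the first point
    (past the core) where every quantity in ``idx_pair`` is below cutoff."""
    if npts <= 1:
        return npts, False
    sub = q[1:npts][:, list(idx_pair)]
    below = np.all(sub < cutoff, axis=1)
    hits = np.nonzero(below)[0]
    if len(hits) == 0:
        return npts, False
    return int(hits[0]) + 2, True


def _ihs_walks(values, core, pos_bp, coord, policy, distance_mode, watch, buffers):
    return {
        step: walk_trajectory(
            values, core, step, pos_bp, policy, distance_mode, watch, buffers=buffers
        )
        for step in (1, -1)
    }


def _unphased_ihs(values, core, pos_bp, coord, policy, distance_mode, buffers=None):
    core_col = values[core]
    n0 = int((core_col == 0).sum())
    n2 = int((core_col == 2).sum())
    if n0 == 0 or n2 == 0:
        return None, "core_class_absent"
    parts = _ihs_walks(
        values, core, pos_bp, coord, policy, distance_mode, _UNPHASED_WATCH, buffers
    )
    ihh = {}
    for c in (0, 2):
        pair = (1 + 2 * c, 2 + 2 * c)
        ihh_e = ihh_c = 0.0
        for step in (1, -1):
            site_idx, q, reason = parts[step]
            length, crossed = _branch_length(q, len(site_idx), pair, policy.cutoff)
            if reason == _kernels.STOP_CHROM_END and not crossed and not policy.trunc_ok:
                return None, "truncated"
            d = _step_distances(site_idx[:length], coord)
            ihh_e += _trapezoid(q[:length, pair[0]], d)
            ihh_c += _trapezoid(q[:length, pair[1]], d)
        ihh[c] = (ihh_e, ihh_c)
    ihh2, cihh2 = ihh[2]
    ihh0, cihh0 = ihh[0]
    if min(ihh2, cihh2, ihh0, cihh0) <= 0.0:
        return None, "zero_ihh"
    return combine_unphased_ihs(ihh2, cihh2, ihh0, cihh0), None


def _phased_ihs(values, core, pos_bp, coord, policy, distance_mode, buffers=None):
    core_col = values[core]
    n0 = int((core_col == 0).sum())
    n1 = int((core_col == 1).sum())
    if n0 == 0 or n1 == 0:
        return None, "core_class_absent"
    parts = _ihs_walks(
        values, core, pos_bp, coord, policy, distance_mode, _PHASED_WATCH, buffers
    )
    ihh = {}
    for c in (0, 1):
        idx = 1 + 2 * c
        total = 0.0
        for step in (1, -1):
            site_idx, q, reason = parts[step]
            length, crossed = _branch_length(q, len(site_idx), (idx,), policy.cutoff)
            if reason == _kernels.STOP_CHROM_END and not crossed and not policy.trunc_ok:
                return None, "truncated"
            d = _step_distances(site_idx[:length], coord)
            total += _trapezoid(q[:length, idx], d)
        ihh[c] = total
    if min(ihh[0], ihh[1]) <= 0.0:
        return None, "zero_ihh"
    # positive when the derived-allele haplotypes are long / low diversity
    return (math.log10(ihh[1]) - math.log10(ihh[0]), ihh[1], ihh[0]), None


def _xp(
    values_a,
    values_b,
    core,
    pos_bp,
    coord,
    policy,
    distance_mode,
    buffers=None,
):
    """Full-sample cross-population log-ratio.  The walk stops once EHH is
    below the cutoff in *both* populations; each population's iHH integrates
    its own curve over the common extent."""
    total_a = total_b = 0.0
    for step in (1, -1):
        sa, qa, ra = walk_trajectory(
            values_a, core, step, pos_bp, policy, distance_mode, _FULL_WATCH,
            buffers=buffers,
        )
        sb, qb, rb = walk_trajectory(
            values_b, core, step, pos_bp, policy, distance_mode, _FULL_WATCH,
            buffers=buffers,
        )
        need = max(len(sa), len(sb))
        if len(sa) < need:
            sa, qa, ra = walk_trajectory(
                values_a, core, step, pos_bp, policy, distance_mode, _FULL_WATCH,
                min_steps=need - 1, buffers=buffers,
            )
        if len(sb) < need:
            sb, qb, rb = walk_trajectory(
                values_b, core, step, pos_bp, policy, distance_mode, _FULL_WATCH,
                min_steps=need - 1, buffers=buffers,
            )
        if (ra == _kernels.STOP_CHROM_END or rb == _kernels.STOP_CHROM_END) and (
            not policy.trunc_ok
        ):
            return None, "truncated"
        length = min(len(sa), len(sb))
        d = _step_distances(sa[:length], coord)
        total_a += _trapezoid(qa[:length, 0], d)
        total_b += _trapezoid(qb[:length, 0], d)
    if total_a <= 0.0 or total_b <= 0.0:
        return None, "zero_ihh"
    return (math.log10(total_a) - math.log10(total_b), total_a, total_b), None


def _as_genotypes(data) -> GenotypeMatrix:
    if isinstance(data, HaplotypeMatrix):
        return collapse_to_genotypes(data)
    if isinstance(data, GenotypeMatrix):
        return data
    raise TypeError("expected a HaplotypeMatrix or GenotypeMatrix")


def _record(sites, core, freq, result, statistic) -> ScoreRecord:
    score, num, den = result
    return ScoreRecord(
        locus_id=str(sites["locus_id"].iloc[core]),
        pos_bp=int(sites["pos_bp"].iloc[core]),
        freq_derived=float(freq),
        ihh_num=num,
        ihh_den=den,
        score=score,
        statistic=statistic,
    )


def _site_op(config: ScanConfig):
    if config.statistic in XP_STATS:
        return _xp
    return _unphased_ihs if config.unphased else _phased_ihs


def unphased_ihs_site(genotypes, sites, core, config: ScanConfig):
    """Unphased iHS at one core site, or None when the site must be skipped
    (absent homozygous class, truncation without trunc_ok, or zero iHH)."""
    gm = _as_genotypes(genotypes)
    pos_bp = sites["pos_bp"].to_numpy(np.int64)
    coord = _distance_coordinate(sites, config.distance_mode)
    result, _ = _unphased_ihs(
        gm.values, core, pos_bp, coord, config.policy, config.distance_mode
    )
    if result is None:
        return None
    freq = gm.values[core].sum(dtype=np.int64) / (2.0 * gm.n)
    return _record(sites, core, freq, result, config.label)


def unphased_nsl_site(genotypes, sites, core, config: ScanConfig):
    """Unphased nSL: identical to unphased iHS with unit (per-site) distances
    and the site-count extension budget."""
    if config.distance_mode != "sites":
        raise ValueError("nSL requires distance_mode='sites'")
    return unphased_ihs_site(genotypes, sites, core, config)


def phased_ihs_site(haps, sites, core, config: ScanConfig):
    if not isinstance(haps, HaplotypeMatrix):
        raise TypeError("phased statistics need a HaplotypeMatrix")
    pos_bp = sites["pos_bp"].to_numpy(np.int64)
    coord = _distance_coordinate(sites, config.distance_mode)
    result, _ = _phased_ihs(
        haps.values, core, pos_bp, coord, config.policy, config.distance_mode
    )
    if result is None:
        return None
    freq = haps.values[core].mean()
    return _record(sites, core, freq, result, config.label)


phased_nsl_site = phased_ihs_site


def unphased_xp_site(genotypes_a, genotypes_b, sites, core, config: ScanConfig):
    """Unphased XP-EHH / XP-nSL at one core site (population A vs B)."""
    ga, gb = _as_genotypes(genotypes_a), _as_genotypes(genotypes_b)
    if ga.n_sites != gb.n_sites:
        raise ValueError("populations must share the same site list")
    pos_bp = sites["pos_bp"].to_numpy(np.int64)
    coord = _distance_coordinate(sites, config.distance_mode)
    result, _ = _xp(
        ga.values, gb.values, core, pos_bp, coord, config.policy, config.distance_mode
    )
    if result is None:
        return None
    freq = ga.values[core].sum(dtype=np.int64) / (2.0 * ga.n)
    return _record(sites, core, freq, result, config.label)


def phased_xp_site(haps_a, haps_b, sites, core, config: ScanConfig):
    if not isinstance(haps_a, HaplotypeMatrix) or not isinstance(haps_b, HaplotypeMatrix):
        raise TypeError("phased statistics need HaplotypeMatrix inputs")
    if haps_a.n_sites != haps_b.n_sites:
        raise ValueError("populations must share the same site list")
    pos_bp = sites["pos_bp"].to_numpy(np.int64)
    coord = _distance_coordinate(sites, config.distance_mode)
    result, _ = _xp(
        haps_a.values, haps_b.values, core, pos_bp, coord, config.policy,
        config.distance_mode,
    )
    if result is None:
        return None
    freq = haps_a.values[core].mean()
    return _record(sites, core, freq, result, config.label)


def records_to_frame(records, statistic: Optional[str] = None) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {
                "locus_id": r.locus_id,
                "pos_bp": r.pos_bp,
                "freq_derived": r.freq_derived,
                "ihh_num": r.ihh_num,
                "ihh_den": r.ihh_den,
                "score": r.score,
            }
            for r in records
        ],
        columns=SCORE_COLUMNS,
    )
    if statistic is not None:
        df.attrs["statistic"] = statistic
    return df


def scan(data, sites, config: ScanConfig, data_b=None) -> pd.DataFrame:
    """Run the configured statistic over every core site passing the MAF
    filter; preserves site order.

    Returns a score DataFrame (columns locus_id, pos_bp, freq_derived,
    ihh_num, ihh_den, score); skipped-site counts by reason are stored in
    ``df.attrs['skipped']``.
    """
    is_xp = config.statistic in XP_STATS
    if is_xp and data_b is None:
        raise ValueError(f"{config.statistic} needs a second population (data_b)")
    if not is_xp and data_b is not None:
        raise ValueError(f"{config.statistic} takes a single population")

    if config.unphased:
        ga = _as_genotypes(data)
        values_a = ga.values
        freqs = ga.values.sum(axis=1, dtype=np.int64) / (2.0 * ga.n)
        mask = filter_core_sites(ga, sites, config.maf_threshold)
        values_b = _as_genotypes(data_b).values if is_xp else None
        if is_xp and values_b.shape[0] != values_a.shape[0]:
            raise ValueError("populations must share the same site list")
    else:
        if not isinstance(data, HaplotypeMatrix):
            raise TypeError("phased statistics need a HaplotypeMatrix")
        values_a = data.values
        freqs = values_a.mean(axis=1)
        maf = np.minimum(freqs, 1.0 - freqs)
        validate_site_table(sites, values_a.shape[0])
        mask = maf >= config.maf_threshold
        values_b = None
        if is_xp:
            if not isinstance(data_b, HaplotypeMatrix):
                raise TypeError("phased statistics need HaplotypeMatrix inputs")
            values_b = data_b.values
            if values_b.shape[0] != values_a.shape[0]:
                raise ValueError("populations must share the same site list")

    pos_bp = sites["pos_bp"].to_numpy(np.int64)
    coord = _distance_coordinate(sites, config.distance_mode)
    S = values_a.shape[0]
    buffers = (
        np.empty(S + 1, np.int64),
        np.empty((S + 1, _kernels.N_QUANT), np.float64),
    )

    if is_xp:
        def compute(core):
            return _xp(
                values_a, values_b, core, pos_bp, coord, config.policy,
                config.distance_mode, buffers,
            )
    elif config.unphased:
        def compute(core):
            return _unphased_ihs(
                values_a, core, pos_bp, coord, config.policy, config.distance_mode,
                buffers,
            )
    else:
        def compute(core):
            return _phased_ihs(
                values_a, core, pos_bp, coord, config.policy, config.distance_mode,
                buffers,
            )

    records = []
    skipped: Counter = Counter()
    skipped["maf_filter"] = int((~mask).sum())
    for core in np.nonzero(mask)[0]:
        result, reason = compute(int(core))
        if result is None:
            skipped[reason] += 1
            continue
        records.append(_record(sites, int(core), freqs[core], result, config.label))

    df = records_to_frame(records, config.label)
    df.attrs["skipped"] = dict(skipped)
    if skipped:
        logger.info(
            "%s scan: %d scored, skipped %s", config.label, len(records), dict(skipped)
        )
    return df
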