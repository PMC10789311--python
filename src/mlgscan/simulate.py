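"""Synthetic haplotype fixtures with neutral and sweep-like structure.

This generator emulates, at desk scale, the features of population samples
that homozygosity-based scans respond to.  It is deliberately *not* a
coalescent-with-selection simulator: the region is split into independent
linkage blocks (block boundaries follow a Poisson process whose intensity is
set by the scaled recombination rate), each block draws its own Kingman
coalescent genealogy, and mutations are dropped on branches proportionally to
branch length.  Within a block nearby sites therefore share genealogy and are
correlated; across blocks they are independent; the site frequency spectrum
is the neutral one, skewed toward rare variants.

A sweep is imposed structurally on a neutral background: round(f * n_hap)
carrier haplotypes receive the derived allele at the core position and copy a
founder haplotype over a tract around the core whose per-side length is
exponential with mean s / (r * ln(4*N*s)) — the classic scaling of a hard
sweep's haplotype footprint, so stronger selection produces longer shared
tracts.  Soft sweeps (e > 0) seed ceil(e * n_hap) distinct founders; g > 0
sprinkles g generations' worth of extra mutations on carrier tracts to mimic
post-fixation decay of the signal.

Defaults correspond to samples of 2n = 200 haplotypes from a population of
effective size 10,000 over L = 500 kbp with mutation rate 2.35e-8 and
recombination rate 1.2e-8 per site per generation (theta_like = 4*N*mu*L =
470, rho_like = 4*N*r*L = 240).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .data_model import HaplotypeMatrix, make_site_table

__all__ = [
    "SweepModel",
    "SimulationParameters",
    "simulate_neutral",
    "simulate_sweep",
    "simulate_two_pops",
    "pair_diploids",
    "scramble_phase",
]


@dataclass
class SweepModel:
    """Sweep parameters: selection coefficient ``s``; start frequency ``e``
    (0 = hard sweep, >0 = soft); sampling frequency ``f`` of the adaptive
    allele; ``g`` generations since fixation (requires f = 1); core position
    in bp (default: middle of the region)."""

    s: float
    e: float = 0.0
    f: float = 1.0
    g: int = 0
    core_pos: Optional[int] = None


@dataclass
class SimulationParameters:
    L: int = 500_000
    n_hap: int = 200
    theta_like: float = 470.0
    rho_like: float = 240.0
    ne: float = 10_000.0
    sweep: Optional[SweepModel] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.L <= 0 or self.n_hap < 2 or self.n_hap % 2 != 0:
            raise ValueError("need L > 0 and an even n_hap >= 2")
        if self.theta_like <= 0 or self.rho_like < 0:
            raise ValueError("theta_like must be > 0 and rho_like >= 0")
        sw = self.sweep
        if sw is not None:
            if not 0.0 <= sw.e < sw.f <= 1.0:
                raise ValueError("sweep frequencies must satisfy 0 <= e < f <= 1")
            if sw.g > 0 and sw.f != 1.0:
                raise ValueError("g > 0 (post-fixation) requires f = 1")
            if sw.core_pos is not None and not 0 < sw.core_pos < self.L:
                raise ValueError("core_pos must lie inside (0, L)")

    @property
    def mu_bp(self) -> float:
        return self.theta_like / (4.0 * self.ne * self.L)

    @property
    def r_bp(self) -> float:
        return self.rho_like / (4.0 * self.ne * self.L)


def _coalescent_block(rng: np.random.Generator, n: int):
    """One Kingman genealogy: returns (parent, node_time, left, right) over
    2n-1 nodes (leaves 0..n-1), times in units of 2N generations."""
    total = 2 * n - 1
    parent = np.full(total, -1, dtype=np.int64)
    node_time = np.zeros(total, dtype=np.float64)
    left = np.empty(n - 1, dtype=np.int64)
    right = np.empty(n - 1, dtype=np.int64)
    ks = np.arange(n, 1, -1, dtype=np.float64)
    waits = rng.exponential(size=n - 1) * (2.0 / (ks * (ks - 1.0)))
    active = list(range(n))
    t = 0.0
    for step in range(n - 1):
        k = n - step
        t += waits[step]
        nv = n + step
        i = int(rng.integers(k))
        a = active[i]
        active[i] = active[-1]
        active.pop()
        j = int(rng.integers(k - 1))
        b = active[j]
        active[j] = nv
        parent[a] = nv
        parent[b] = nv
        left[step] = a
        right[step] = b
        node_time[nv] = t
    return parent, node_time, left, right


def _leaves_under(node: int, n: int, left, right) -> np.ndarray:
    stack = [node]
    out = []
    while stack:
        v = stack.pop()
        if v < n:
            out.append(v)
        else:
            stack.append(left[v - n])
            stack.append(right[v - n])
    return np.asarray(out, dtype=np.int64)


def _neutral_block(rng, n, theta_block):
    """Simulate one linkage block; returns (relative positions in [0,1),
    allele matrix (n_mut, n))."""
    parent, node_time, left, right = _coalescent_block(rng, n)
    blen = node_time[parent] - node_time  # root keeps parent -1: fix below
    blen[2 * n - 2] = 0.0
    total_len = blen.sum()
    n_mut = rng.poisson(0.5 * theta_block * total_len)
    if n_mut == 0:
        return np.empty(0), np.empty((0, n), dtype=np.int8)
    nodes = rng.choice(2 * n - 1, size=n_mut, p=blen / total_len)
    alleles = np.zeros((n_mut, n), dtype=np.int8)
    for i, node in enumerate(nodes):
        alleles[i, _leaves_under(int(node), n, left, right)] = 1
    rel = rng.random(n_mut)
    order = np.argsort(rel, kind="stable")
    return rel[order], alleles[order]


def _simulate_neutral_values(params: SimulationParameters, rng: np.random.Generator):
    L, n = params.L, params.n_hap
    n_breaks = rng.poisson(params.rho_like / 2.0)
    breaks = np.sort(rng.integers(1, L, size=n_breaks))
    edges = np.concatenate(([0], breaks, [L]))
    positions = []
    blocks = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        if hi <= lo:
            continue
        theta_block = params.theta_like * (hi - lo) / L
        rel, alleles = _neutral_block(rng, n, theta_block)
        if len(rel) == 0:
            continue
        positions.append(lo + rel * (hi - lo))
        blocks.append(alleles)
    if not positions:
        return np.empty(0, dtype=np.int64), np.empty((0, n), dtype=np.int8)
    pos = np.concatenate(positions)
    values = np.concatenate(blocks, axis=0)
    # to integer 1-based bp, deduplicated, strictly increasing
    pos_bp = np.floor(pos).astype(np.int64) + 1
    keep = np.concatenate(([True], np.diff(pos_bp) > 0))
    return pos_bp[keep], values[keep]


def simulate_neutral(params: SimulationParameters):
    """Neutral sample: returns (HaplotypeMatrix, site table).  Deterministic
    given ``params.seed``."""
    rng = np.random.default_rng(params.seed)
    pos_bp, values = _simulate_neutral_values(params, rng)
    sites = make_site_table(pos_bp)
    return HaplotypeMatrix(values), sites


def _impose_sweep(values, pos_bp, params: SimulationParameters, cols, rng):
    """Overwrite a sweep footprint onto neutral haplotypes for the haplotype
    columns in ``cols``; returns (values, pos_bp) with the core site added."""
    sw = params.sweep
    n_pop = len(cols)
    core_pos = sw.core_pos if sw.core_pos is not None else params.L // 2
    n_car = int(round(sw.f * n_pop))
    if n_car < 1:
        raise ValueError("f * n_hap < 1: sweep has no carriers")

    carriers = rng.permutation(n_pop)[:n_car]
    n_founders = max(1, math.ceil(sw.e * n_pop)) if sw.e > 0 else 1
    n_founders = min(n_founders, n_car)
    founders = carriers[:n_founders]
    founder_of = founders[rng.integers(n_founders, size=n_car)]
    founder_of[:n_founders] = founders  # each founder copies itself

    denom = max(math.log(4.0 * params.ne * sw.s), 1.0)
    mean_tract = sw.s / (params.r_bp * denom)

    values = values.copy()
    tract_bounds = np.empty((n_car, 2), dtype=np.int64)
    for k in range(n_car):
        lo = core_pos - rng.exponential(mean_tract)
        hi = core_pos + rng.exponential(mean_tract)
        tract_bounds[k] = (max(int(lo), 0), min(int(hi), params.L))
    for k in range(n_car):
        car, fnd = cols[carriers[k]], cols[founder_of[k]]
        inside = (pos_bp >= tract_bounds[k, 0]) & (pos_bp <= tract_bounds[k, 1])
        values[inside, car] = values[inside, fnd]

    if sw.g > 0:
        for k in range(n_car):
            lo, hi = tract_bounds[k]
            lam = params.mu_bp * sw.g * (hi - lo)
            n_new = rng.poisson(lam)
            if n_new == 0:
                continue
            inside = np.nonzero((pos_bp >= lo) & (pos_bp <= hi))[0]
            if len(inside) == 0:
                continue
            flips = rng.choice(inside, size=min(n_new, len(inside)), replace=False)
            car = cols[carriers[k]]
            values[flips, car] = 1 - values[flips, car]

    # insert the selected core site (derived in carriers only)
    core_bp = int(core_pos)
    while core_bp in pos_bp:
        core_bp += 1
    idx = int(np.searchsorted(pos_bp, core_bp))
    core_row = np.zeros((1, values.shape[1]), dtype=np.int8)
    core_row[0, cols[carriers]] = 1
    values = np.concatenate([values[:idx], core_row, values[idx:]], axis=0)
    pos_bp = np.concatenate([pos_bp[:idx], [core_bp], pos_bp[idx:]])
    return values, pos_bp, core_bp


def simulate_sweep(params: SimulationParameters):
    """Sweep sample: neutral background plus an imposed sweep footprint.
    Returns (HaplotypeMatrix, site table); the core site carries the derived
    allele in exactly round(f * n_hap) haplotypes."""
    if params.sweep is None:
        raise ValueError("params.sweep must be set")
    rng = np.random.default_rng(params.seed)
    pos_bp, values = _simulate_neutral_values(params, rng)
    cols = np.arange(params.n_hap)
    values, pos_bp, _ = _impose_sweep(values, pos_bp, params, cols, rng)
    return HaplotypeMatrix(values), make_site_table(pos_bp)


def simulate_two_pops(
    params: SimulationParameters,
    n_hap_b: Optional[int] = None,
    sweep_in_pop_a: bool = True,
):
    """Two samples sharing one site table (drawn from a common background so
    both populations are genotyped at the same loci); an optional sweep is
    imposed on population A (or B).  Returns (haps_a, haps_b, sites)."""
    n_a = params.n_hap
    n_b = n_hap_b if n_hap_b is not None else n_a
    if n_b < 2 or n_b % 2 != 0:
        raise ValueError("n_hap_b must be an even number >= 2")
    from dataclasses import replace

    joint = replace(params, n_hap=n_a + n_b, sweep=None)
    rng = np.random.default_rng(params.seed)
    pos_bp, values = _simulate_neutral_values(joint, rng)
    if params.sweep is not None:
        cols = np.arange(n_a) if sweep_in_pop_a else np.arange(n_a, n_a + n_b)
        # carrier frequency f applies within the swept population
        swept = replace(params, n_hap=len(cols))
        values, pos_bp, _ = _impose_sweep(values, pos_bp, swept, cols, rng)
    sites = make_site_table(pos_bp)
    return (
        HaplotypeMatrix(values[:, :n_a]),
        HaplotypeMatrix(values[:, n_a:]),
        sites,
    )


def pair_diploids(haps: HaplotypeMatrix, seed: int) -> HaplotypeMatrix:
    """Randomly pair haplotypes into diploids: a seeded permutation of the
    columns, after which consecutive pairs form individuals."""
    if haps.n_haplotypes % 2 != 0:
        raise ValueError("odd haplotype count cannot be paired")
    perm = np.random.default_rng(seed).permutation(haps.n_haplotypes)
    return HaplotypeMatrix(haps.values[:, perm])


def scramble_phase(haps: HaplotypeMatrix, p: float = 0.5, seed: int = 0) -> HaplotypeMatrix:
    """Destroy phase: independently for every heterozygous site-individual
    cell, swap the two alleles between the individual's haplotypes with
    probability ``p``.  Genotypes (allele counts) are unchanged."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    if haps.n_haplotypes % 2 != 0:
        raise ValueError("matrix must contain paired haplotypes")
    rng = np.random.default_rng(seed)
    a = haps.values[:, 0::2]
    b = haps.values[:, 1::2]
    swap = (a != b) & (rng.random(a.shape) < p)
    new_a = np.where(swap, b, a)
    new_b = np.where(swap, a, b)
    out = np.empty_like(haps.values)
    out[:, 0::2] = new_a
    out[:, 1::2] = new_b
    return HaplotypeMatrix(out)
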