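"""Extended haplotype homozygosity (EHH) on multi-locus genotypes.

For a sample of m sequences (diploid multi-locus genotypes over {0,1,2}, or
phased haplotypes over {0,1}) and a core site x0, let C_xi be the set of
distinct extended sequences spanning x0..xi.  With n_h copies of type h:

    EHH(x_i)    = sum_h n_h^2 / m^2                       (full sample)
    EHH_c(x_i)  = sum_{h with core value c} n_h^2 / n_c^2  (core-conditioned)
    cEHH_c(x_i) = sum_{h with core value != c} n_h^2 / n_c'^2  (complement)

EHH_c equals 1 at the core; full-sample EHH at the core is sum_c n_c^2 / m^2,
which is below 1 whenever the core is polymorphic.  All three are
non-increasing away from the core because extending by a site only splits
sequence classes.

Decay curves are integrated into iHH by the trapezoid rule over a distance
measure: basepairs, centimorgans, or one unit per site (the nSL convention).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

from . import _kernels
from .data_model import GenotypeMatrix, HaplotypeMatrix, validate_site_table

__all__ = [
    "ExtensionPolicy",
    "EHHCurve",
    "UndefinedCoreError",
    "ehh_full",
    "ehh_core",
    "cehh_core",
    "ehh_decay_curve",
    "integrate_ihh",
]


class UndefinedCoreError(ValueError):
    """The requested core class (or its complement) has no members; the caller
    should skip this core/statistic."""


@dataclass(frozen=True)
class ExtensionPolicy:
    """Stopping rules for EHH decay walks.

    cutoff            stop once the tracked EHH values fall below this
    max_gap_bp        stop before crossing an inter-site gap larger than this
    max_extend_bp     stop before extending further than this from the core
                      (bp/cM distance modes only)
    max_extend_sites  per-direction site budget (sites distance mode only)
    trunc_ok          accept curves cut short by the chromosome edge; when
                      False such cores are skipped
    """

    cutoff: float = 0.05
    max_gap_bp: int = 200_000
    max_extend_bp: int = 1_000_000
    max_extend_sites: int = 100
    trunc_ok: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.cutoff < 1.0:
            raise ValueError("cutoff must be in [0, 1)")


@dataclass
class EHHCurve:
    """One direction of an EHH decay curve.  The first point is the core site
    (distance 0).  ``cehh`` is None for full-sample curves."""

    direction: str  # "up" (increasing index) or "down"
    sites: np.ndarray  # site indices, starting at the core
    distances: np.ndarray  # d(x_{i-1}, x_i); first entry 0
    ehh: np.ndarray
    cehh: Optional[np.ndarray]
    truncated: bool

    def __len__(self) -> int:
        return len(self.sites)


def _values(matrix) -> np.ndarray:
    if isinstance(matrix, (GenotypeMatrix, HaplotypeMatrix)):
        return matrix.values
    return np.ascontiguousarray(matrix, dtype=np.int8)


def _homozygosity(sub: np.ndarray) -> float:
    _, counts = np.unique(sub, axis=1, return_counts=True)
    m = sub.shape[1]
    return float((counts.astype(np.int64) ** 2).sum()) / (m * m)


def _span(values: np.ndarray, core: int, extent: int) -> np.ndarray:
    lo, hi = (core, extent) if core <= extent else (extent, core)
    return values[lo : hi + 1]


def ehh_full(matrix, core: int, extent: int) -> float:
    """Full-sample EHH over the inclusive span core..extent."""
    values = _values(matrix)
    if values.shape[1] < 2:
        raise ValueError("need at least 2 sequences")
    return _homozygosity(_span(values, core, extent))


def ehh_core(matrix, core: int, c: int, extent: int) -> float:
    """EHH among the n_c sequences whose core value equals ``c``."""
    values = _values(matrix)
    mask = values[core] == c
    if not mask.any():
        raise UndefinedCoreError(f"no sequences with core value {c}")
    return _homozygosity(_span(values, core, extent)[:, mask])


def cehh_core(matrix, core: int, c: int, extent: int) -> float:
    """Complement EHH: homozygosity among sequences whose core value is not
    ``c``.  Below 1 at the core whenever the complement spans more than one
    core class."""
    values = _values(matrix)
    mask = values[core] != c
    if not mask.any():
        raise UndefinedCoreError(f"no sequences with core value != {c}")
    return _homozygosity(_span(values, core, extent)[:, mask])


def _distance_coordinate(sites: pd.DataFrame, distance_mode: str) -> np.ndarray:
    if distance_mode == "bp":
        return sites["pos_bp"].to_numpy(dtype=np.float64)
    if distance_mode == "cm":
        if "pos_cm" not in sites.columns:
            raise ValueError("distance_mode='cm' requires a pos_cm column (read a map file)")
        return sites["pos_cm"].to_numpy(dtype=np.float64)
    if distance_mode == "sites":
        return np.arange(len(sites), dtype=np.float64)
    raise ValueError(f"unknown distance_mode {distance_mode!r}")


def _kernel_limits(policy: ExtensionPolicy, distance_mode: str) -> tuple[int, int]:
    """(max_extend_bp, max_steps) as the kernel expects them."""
    if distance_mode == "sites":
        return np.iinfo(np.int64).max // 4, policy.max_extend_sites
    return policy.max_extend_bp, -1


def walk_trajectory(
    values: np.ndarray,
    core: int,
    step: int,
    pos_bp: np.ndarray,
    policy: ExtensionPolicy,
    distance_mode: str,
    watch_idx,
    min_steps: int = 0,
    buffers=None,
):
    """Run the JIT walk; return (site indices, quantity matrix, stop reason).

    ``watch_idx`` selects which of the seven kernel quantities keep the walk
    alive (see :mod:`mlgscan._kernels` for the layout).
    """
    S = values.shape[0]
    if buffers is None:
        site_buf = np.empty(S + 1, np.int64)
        q_buf = np.empty((S + 1, _kernels.N_QUANT), np.float64)
    else:
        site_buf, q_buf = buffers
    watch = np.zeros(_kernels.N_QUANT, np.bool_)
    watch[list(watch_idx)] = True
    max_extend_bp, max_steps = _kernel_limits(policy, distance_mode)
    npts, reason = _kernels.ehh_walk(
        values,
        core,
        step,
        pos_bp,
        policy.cutoff,
        policy.max_gap_bp,
        max_extend_bp,
        max_steps,
        watch,
        min_steps,
        site_buf,
        q_buf,
    )
    return site_buf[:npts].copy(), q_buf[:npts].copy(), reason


def _step_distances(site_idx: np.ndarray, coord: np.ndarray) -> np.ndarray:
    d = np.zeros(len(site_idx), dtype=np.float64)
    if len(site_idx) > 1:
        d[1:] = np.abs(np.diff(coord[site_idx]))
    return d


def ehh_decay_curve(
    matrix,
    core: int,
    c: Optional[int],
    policy: ExtensionPolicy,
    sites: pd.DataFrame,
    distance_mode: str = "bp",
) -> tuple[EHHCurve, EHHCurve]:
    """EHH decay curves in both directions from ``core``.

    With ``c`` given, curves carry EHH_c and cEHH_c and the walk runs until
    both fall below the cutoff; with ``c=None`` the full-sample EHH is tracked.
    Returns (upstream curve, downstream curve) where upstream walks toward
    larger positions.
    """
    values = _values(matrix)
    validate_site_table(sites, values.shape[0])
    pos_bp = sites["pos_bp"].to_numpy(dtype=np.int64)
    coord = _distance_coordinate(sites, distance_mode)

    if c is None:
        watch_idx = (0,)
    else:
        if not (values[core] == c).any():
            raise UndefinedCoreError(f"no sequences with core value {c}")
        watch_idx = (1 + 2 * c, 2 + 2 * c)

    curves = []
    for name, step in (("up", 1), ("down", -1)):
        site_idx, q, reason = walk_trajectory(
            values, core, step, pos_bp, policy, distance_mode, watch_idx
        )
        if c is None:
            ehh_vals = q[:, 0]
            cehh_vals = None
        else:
            ehh_vals = q[:, 1 + 2 * c]
            cehh_vals = q[:, 2 + 2 * c]
        curves.append(
            EHHCurve(
                direction=name,
                sites=site_idx,
                distances=_step_distances(site_idx, coord),
                ehh=ehh_vals,
                cehh=cehh_vals,
                truncated=reason == _kernels.STOP_CHROM_END,
            )
        )
    return curves[0], curves[1]


def _trapezoid(values: np.ndarray, distances: np.ndarray) -> float:
    if len(values) < 2:
        return 0.0
    return float(np.sum(0.5 * (values[:-1] + values[1:]) * distances[1:]))


def integrate_ihh(
    curve_up: EHHCurve,
    curve_down: EHHCurve,
    field: str = "ehh",
    trunc_ok: bool = False,
) -> Optional[float]:
    """Trapezoid-integrate a pair of decay curves into iHH.

    Units follow the curve's distance mode (EHH*bp, EHH*cM, or EHH*sites).
    Returns None (a skip signal) when a curve was cut off by the chromosome
    edge and ``trunc_ok`` is unset.  A direction with no extension contributes
    0.
    """
    if curve_up.sites[0] != curve_down.sites[0]:
        raise ValueError("curves do not share a core point")
    if not trunc_ok and (curve_up.truncated or curve_down.truncated):
        return None
    total = 0.0
    for curve in (curve_up, curve_down):
        vals = curve.ehh if field == "ehh" else curve.cehh
        if vals is None:
            raise ValueError("curve has no complement values")
        total += _trapezoid(vals, curve.distances)
    return total


def with_cutoff(policy: ExtensionPolicy, cutoff: float) -> ExtensionPolicy:
    return replace(policy, cutoff=cutoff)
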