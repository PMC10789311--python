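"""Score standardization.

iHS and nSL scores are standardized within derived-allele-frequency bins
(1% bins by default): within each bin, z = (x - mean) / sd with the population
(divide-by-count) standard deviation.  XP-EHH and XP-nSL are standardized
genome-wide, i.e. in a single bin.  For simulation studies, each replicate is
standardized *jointly* with a background of neutral replicates: moments are
estimated on the pooled records, then applied to the target alone.

Standardized frames gain two columns: ``std_score`` (NaN where the bin was
unstandardizable — fewer than two records or zero spread) and ``extreme``
(1.0 where |std_score| exceeds the critical value, 0.0 otherwise, NaN where
std_score is NaN).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["normalize_freq_bins", "normalize_genomewide", "joint_normalize"]


def _as_list(frames):
    if isinstance(frames, pd.DataFrame):
        return [frames], True
    return list(frames), False


def _bin_index(freq: np.ndarray, n_bins: int) -> np.ndarray:
    # bins [k/n, (k+1)/n) with the last bin closed at 1.0
    idx = np.floor(freq * n_bins).astype(np.int64)
    return np.clip(idx, 0, n_bins - 1)


def _standardize(frames, n_bins: int, crit_value: float):
    frames, single = _as_list(frames)
    for df in frames:
        for col in ("freq_derived", "score"):
            if col not in df.columns:
                raise ValueError(f"score frame missing column {col!r}")

    pooled_freq = np.concatenate([df["freq_derived"].to_numpy(float) for df in frames])
    pooled_score = np.concatenate([df["score"].to_numpy(float) for df in frames])
    pooled_bin = _bin_index(pooled_freq, n_bins)

    means = np.full(n_bins, np.nan)
    sds = np.full(n_bins, np.nan)
    flagged = 0
    for b in range(n_bins):
        sel = pooled_score[pooled_bin == b]
        if len(sel) < 2:
            flagged += len(sel)
            continue
        sd = float(sel.std(ddof=0))
        if sd == 0.0:
            flagged += len(sel)
            continue
        means[b] = float(sel.mean())
        sds[b] = sd
    if flagged:
        logger.info("normalization: %d records in unstandardizable bins", flagged)

    out = []
    for df in frames:
        res = df.copy()
        b = _bin_index(res["freq_derived"].to_numpy(float), n_bins)
        z = (res["score"].to_numpy(float) - means[b]) / sds[b]
        res["std_score"] = z
        extreme = np.where(np.abs(z) > crit_value, 1.0, 0.0)
        extreme[np.isnan(z)] = np.nan
        res["extreme"] = extreme
        res.attrs = dict(df.attrs)
        res.attrs["crit_value"] = crit_value
        out.append(res)
    return out[0] if single else out


def normalize_freq_bins(frames, n_bins: int = 100, crit_value: float = 2.0):
    """Standardize scores within equal-width derived-allele-frequency bins,
    pooling all input frames for moment estimation.  Accepts one frame or a
    list; returns the same shape with ``std_score``/``extreme`` added."""
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    return _standardize(frames, n_bins, crit_value)


def normalize_genomewide(frames, crit_value: float = 2.0):
    """Single-bin standardization over the pooled records (the XP-EHH /
    XP-nSL convention)."""
    flist, _ = _as_list(frames)
    total = sum(len(df) for df in flist)
    if total < 2:
        raise ValueError("genome-wide normalization needs at least 2 records")
    return _standardize(frames, 1, crit_value)


def joint_normalize(
    target: pd.DataFrame,
    background,
    mode: str = "bins",
    n_bins: int = 100,
    crit_value: float = 2.0,
) -> pd.DataFrame:
    """Standardize ``target`` using moments estimated from target plus
    background frames pooled (e.g. one sweep replicate against all neutral
    replicates); only the standardized target is returned."""
    background, _ = _as_list(background) if background is not None else ([], False)
    frames = [target] + background
    if mode == "bins":
        return normalize_freq_bins(frames, n_bins=n_bins, crit_value=crit_value)[0]
    if mode == "genomewide":
        return normalize_genomewide(frames, crit_value=crit_value)[0]
    raise ValueError(f"unknown mode {mode!r}")
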