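"""Window-based sweep calling, power and false positive rate.

Because extreme scores cluster along the genome near a sweep, calling operates
on windows rather than single sites: standardized scores are grouped into
non-overlapping 100 kbp windows, each window is summarized by the proportion
of extreme scores (|z| > 2 by default), windows are stratified into 10
quantile bins by the number of scores they contain (homozygosity statistics
yield fewer scores in low-recombination / low-diversity regions), and the top
1% of windows by extreme-score proportion is called within each bin.

Power is the fraction of sweep replicates whose window containing the sweep
site is called.  The false positive rate is the fraction of neutral
replicates whose focal window (the analogue of the sweep window, at the
centre of the simulated region) is called; counting a neutral replicate as a
false positive when *any* of its windows is called is available by passing
``focal_pos_bp=None``.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "window_proportions",
    "assign_quantile_bins",
    "call_top_percent",
    "compute_power",
    "compute_fpr",
    "per_replicate_call_rate",
]

WINDOW_COLUMNS = [
    "replicate_id",
    "window_start",
    "n_scores",
    "n_extreme",
    "proportion",
]


def window_proportions(
    scores: pd.DataFrame,
    window_bp: int = 100_000,
    threshold: float = 2.0,
    two_sided: bool = True,
    replicate_col: str = "replicate_id",
) -> pd.DataFrame:
    """Proportion of extreme standardized scores per non-overlapping window.

    ``scores`` needs ``pos_bp`` and ``std_score`` columns (records with NaN
    std_score — unstandardizable bins — are ignored) and optionally a
    replicate identifier column.  Windows are half-open [k*window_bp,
    (k+1)*window_bp); windows without any score are excluded.
    """
    df = scores
    if replicate_col not in df.columns:
        df = df.copy()
        df[replicate_col] = 0
    z = df["std_score"].to_numpy(float)
    keep = ~np.isnan(z)
    df = df.loc[keep]
    z = z[keep]
    extreme = np.abs(z) > threshold if two_sided else z > threshold

    win = (df["pos_bp"].to_numpy(np.int64) // window_bp) * window_bp
    agg = (
        pd.DataFrame(
            {
                "replicate_id": df[replicate_col].to_numpy(),
                "window_start": win,
                "extreme": extreme.astype(np.int64),
            }
        )
        .groupby(["replicate_id", "window_start"], sort=True)
        .agg(n_scores=("extreme", "size"), n_extreme=("extreme", "sum"))
        .reset_index()
    )
    agg["proportion"] = agg["n_extreme"] / agg["n_scores"]
    return agg[WINDOW_COLUMNS]


def assign_quantile_bins(windows: pd.DataFrame, n_bins: int = 10) -> pd.DataFrame:
    """Stratify windows into quantile bins by the number of scores observed.

    Windows are ranked by ``n_scores`` with ties resolved by the stable
    (replicate_id, window_start) order; bin k collects ranks in
    [k*N/n_bins, (k+1)*N/n_bins).  With fewer windows than bins everything
    lands in bin 0 (logged).
    """
    out = windows.reset_index(drop=True).copy()
    n = len(out)
    if n == 0:
        out["quantile_bin"] = pd.Series(dtype=np.int64)
        return out
    if n < n_bins:
        logger.info("only %d windows for %d quantile bins; using a single bin", n, n_bins)
        out["quantile_bin"] = 0
        return out
    order = np.argsort(out["n_scores"].to_numpy(), kind="stable")
    rank = np.empty(n, dtype=np.int64)
    rank[order] = np.arange(n)
    out["quantile_bin"] = rank * n_bins // n
    return out


def call_top_percent(windows: pd.DataFrame, top_fraction: float = 0.01) -> pd.DataFrame:
    """Flag the top ``top_fraction`` of windows by extreme-score proportion
    within each quantile bin; exactly ceil(top_fraction * bin size) windows
    are called per bin, ties broken by larger n_extreme then stable order."""
    if "quantile_bin" not in windows.columns:
        raise ValueError("assign_quantile_bins must run before call_top_percent")
    out = windows.reset_index(drop=True).copy()
    called = np.zeros(len(out), dtype=bool)
    for _, grp in out.groupby("quantile_bin", sort=False):
        k = math.ceil(top_fraction * len(grp))
        ranked = grp.sort_values(
            ["proportion", "n_extreme"], ascending=False, kind="mergesort"
        )
        called[ranked.index[:k]] = True
    out["called"] = called
    return out


def _window_of(pos_bp: int, window_bp: int) -> int:
    return (int(pos_bp) // window_bp) * window_bp


def compute_power(
    windows: pd.DataFrame,
    nonneutral_ids,
    sweep_pos_bp: int,
    window_bp: int = 100_000,
) -> float:
    """Fraction of non-neutral replicates whose window containing the sweep
    site is called."""
    ids = list(nonneutral_ids)
    if not ids:
        raise ValueError("no non-neutral replicates")
    target = _window_of(sweep_pos_bp, window_bp)
    called = windows.loc[windows["called"] & (windows["window_start"] == target)]
    hit = set(called["replicate_id"])
    return sum(r in hit for r in ids) / len(ids)


def compute_fpr(
    windows: pd.DataFrame,
    neutral_ids,
    focal_pos_bp: int | None = None,
    window_bp: int = 100_000,
) -> float:
    """Fraction of neutral replicates falling in the called top fraction.

    With ``focal_pos_bp`` set (the centre of the simulated region — the
    position where a sweep would sit), a neutral replicate counts as a false
    positive when its focal window is called, mirroring how power credits the
    sweep window.  With ``focal_pos_bp=None`` any called window makes the
    replicate a false positive.
    """
    ids = list(neutral_ids)
    if not ids:
        raise ValueError("no neutral replicates")
    called = windows.loc[windows["called"]]
    if focal_pos_bp is not None:
        target = _window_of(focal_pos_bp, window_bp)
        called = called.loc[called["window_start"] == target]
    hit = set(called["replicate_id"])
    return sum(r in hit for r in ids) / len(ids)


def per_replicate_call_rate(
    windows: pd.DataFrame,
    target_ids,
    background_ids,
    focal_pos_bp: int | None,
    n_bins: int = 10,
    top_fraction: float = 0.01,
    window_bp: int = 100_000,
) -> float:
    """Fraction of target replicates whose focal window lands in the called
    top fraction when that replicate is evaluated *individually* against the
    background (neutral) windows.

    Each target's windows are pooled with all background windows, quantile
    bins are assigned, the top fraction per bin is called, and the target's
    focal window (containing ``focal_pos_bp``; any window when None) is
    checked.  Targets that are themselves part of the background (neutral
    false-positive evaluation) are evaluated within the pooled background
    call set.  Evaluating replicates one at a time keeps targets from
    competing with each other for the fixed calling quota, so the rate over
    sweep replicates is a power estimate against a purely neutral reference
    distribution.
    """
    targets = list(target_ids)
    if not targets:
        raise ValueError("no target replicates")
    background_set = set(background_ids)
    background = windows.loc[windows["replicate_id"].isin(background_set)]

    def evaluate(table, rid):
        called = call_top_percent(
            assign_quantile_bins(table, n_bins=n_bins), top_fraction=top_fraction
        )
        if focal_pos_bp is None:
            return compute_fpr(called, [rid], focal_pos_bp=None, window_bp=window_bp) > 0
        return (
            compute_power(called, [rid], focal_pos_bp, window_bp=window_bp) > 0
        )

    pooled_background_called = None
    hits = 0
    for rid in targets:
        if rid in background_set:
            if pooled_background_called is None:
                pooled_background_called = call_top_percent(
                    assign_quantile_bins(background, n_bins=n_bins),
                    top_fraction=top_fraction,
                )
            table_called = pooled_background_called
            if focal_pos_bp is None:
                hit = compute_fpr(table_called, [rid], None, window_bp) > 0
            else:
                hit = compute_power(table_called, [rid], focal_pos_bp, window_bp) > 0
        else:
            table = pd.concat(
                [background, windows.loc[windows["replicate_id"] == rid]],
                ignore_index=True,
            )
            hit = evaluate(table, rid)
        hits += hit
    return hits / len(targets)
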