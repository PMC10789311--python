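"""JIT-compiled inner loop for EHH decay walks.

The walk extends site by site away from a core, maintaining a partition of the
sample into classes of identical extended sequences.  Adding a site can only
split classes (never merge), so class labels are refined incrementally in O(m)
per site instead of re-hashing full substrings.

At every recorded point seven homozygosity statistics are evaluated from the
same partition (NaN where the conditioning class is empty):

    index 0: full-sample EHH            sum n_h^2 / m^2
    index 1: EHH_0   (core class 0)     sum over classes with core value 0 / n_0^2
    index 2: cEHH_0  (complement of 0)
    index 3: EHH_1
    index 4: cEHH_1
    index 5: EHH_2
    index 6: cEHH_2

Classes are homogeneous at the core (the core column is part of the extended
sequence), so restricting the full partition to one core value is exactly the
core-conditioned partition.

Stop reasons: 0 cutoff reached, 1 chromosome end, 2 gap limit, 3 extension
limit (bp), 4 extension limit (site count).  Only reason 1 marks a curve as
truncated in the sense of the --trunc-ok convention.
"""

import numpy as np
from numba import njit

N_QUANT = 7

STOP_CUTOFF = 0
STOP_CHROM_END = 1
STOP_GAP = 2
STOP_MAX_BP = 3
STOP_MAX_SITES = 4


@njit(cache=True)
def ehh_walk(
    G,
    core,
    step,
    pos_bp,
    cutoff,
    max_gap_bp,
    max_extend_bp,
    max_steps,
    watch,
    min_steps,
    site_buf,
    q_buf,
):
    """Walk from ``core`` in direction ``step`` (+1/-1), recording the seven
    homozygosity quantities at the core and at each extension site.

    Extension continues while any watched quantity is >= cutoff (the crossing
    point itself is recorded before stopping) and at least ``min_steps``
    extension points have been recorded, subject to the gap / extent / site
    limits.  Returns (number of recorded points, stop reason).
    """
    S, m = G.shape
    core_col = G[core]

    ng = np.zeros(3, np.int64)
    for i in range(m):
        ng[core_col[i]] += 1

    labels = np.empty(m, np.int64)
    lookup = np.empty(3 * m, np.int64)
    counts = np.empty(m, np.int64)
    cls_grp = np.empty(m, np.int64)

    # initial partition: the core column itself
    for k in range(3):
        lookup[k] = -1
    nclass = 0
    for i in range(m):
        g = core_col[i]
        if lookup[g] < 0:
            lookup[g] = nclass
            nclass += 1
        labels[i] = lookup[g]

    npts = 0
    j = core
    steps = 0
    reason = STOP_CUTOFF
    while True:
        for c in range(nclass):
            counts[c] = 0
        for i in range(m):
            c = labels[i]
            counts[c] += 1
            cls_grp[c] = core_col[i]
        ssq_tot = 0
        ssq = np.zeros(3, np.int64)
        for c in range(nclass):
            s2 = counts[c] * counts[c]
            ssq_tot += s2
            ssq[cls_grp[c]] += s2

        q_buf[npts, 0] = ssq_tot / (m * m)
        for g in range(3):
            if ng[g] > 0:
                q_buf[npts, 1 + 2 * g] = ssq[g] / (ng[g] * ng[g])
            else:
                q_buf[npts, 1 + 2 * g] = np.nan
            nc = m - ng[g]
            if nc > 0:
                q_buf[npts, 2 + 2 * g] = (ssq_tot - ssq[g]) / (nc * nc)
            else:
                q_buf[npts, 2 + 2 * g] = np.nan
        site_buf[npts] = j
        npts += 1

        watching = False
        for q in range(N_QUANT):
            if watch[q] and q_buf[npts - 1, q] >= cutoff:
                watching = True
                break
        if steps >= min_steps and not watching:
            reason = STOP_CUTOFF
            break

        nxt = j + step
        if nxt < 0 or nxt >= S:
            reason = STOP_CHROM_END
            break
        if max_steps >= 0 and steps >= max_steps:
            reason = STOP_MAX_SITES
            break
        gap = pos_bp[nxt] - pos_bp[j]
        if gap < 0:
            gap = -gap
        if gap > max_gap_bp:
            reason = STOP_GAP
            break
        ext = pos_bp[nxt] - pos_bp[core]
        if ext < 0:
            ext = -ext
        if ext > max_extend_bp:
            reason = STOP_MAX_BP
            break

        # refine the partition with the next column
        col = G[nxt]
        for k in range(3 * nclass):
            lookup[k] = -1
        newn = 0
        for i in range(m):
            key = labels[i] * 3 + col[i]
            if lookup[key] < 0:
                lookup[key] = newn
                newn += 1
            labels[i] = lookup[key]
        nclass = newn
        j = nxt
        steps += 1

    return npts, reason
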