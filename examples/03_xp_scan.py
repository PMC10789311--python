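"""Cross-population XP-nSL scan on unphased data.

Simulates two samples sharing one site list, imposes a sweep in population A
only, computes unphased XP-nSL (A vs B), standardizes genome-wide, and shows
that large positive scores pile up near the swept core.
"""

import numpy as np

import mlgscan as m
from mlgscan.statistics import ScanConfig

params = m.SimulationParameters(
    L=500_000, n_hap=200, seed=21, sweep=m.SweepModel(s=0.02, f=0.9),
)
haps_a, haps_b, sites = m.simulate_two_pops(params)

config = ScanConfig(statistic="xpnsl", unphased=True,
                    policy=m.ExtensionPolicy(trunc_ok=True))
scores = m.scan(m.collapse_to_genotypes(haps_a), sites, config,
                data_b=m.collapse_to_genotypes(haps_b))
normed = m.normalize_genomewide(scores)

z = normed["std_score"].to_numpy()
pos = normed["pos_bp"].to_numpy()
near = np.abs(pos - 250_000) < 50_000
far = ~near
print(f"{len(normed)} core sites scored (XP-nSL, population A vs B)")
print(f"mean z within 50 kbp of the sweep: {z[near].mean():+.2f}")
print(f"mean z elsewhere:                  {z[far].mean():+.2f}")
print(f"sites with z > 2 near sweep: {(z[near] > 2).sum()} / {near.sum()}")
print("\nPositive XP-nSL means longer high-frequency haplotypes in population")
print("A; the sweep at 250 kbp drives a one-sided cluster of extreme scores.")
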