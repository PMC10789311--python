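"""Single-population unphased nSL scan, standardized in frequency bins.

Builds a sweep replicate plus a small neutral background, scans unphased nSL
(distance measured in sites), jointly standardizes the sweep replicate
against the neutral background in 1% derived-allele-frequency bins, and
prints the most extreme scores.
"""

import mlgscan as m
from mlgscan.statistics import ScanConfig

config = ScanConfig(statistic="nsl", unphased=True,
                    policy=m.ExtensionPolicy(trunc_ok=True))


def scan_one(seed, sweep=None):
    params = m.SimulationParameters(L=500_000, n_hap=200, seed=seed, sweep=sweep)
    haps, sites = (m.simulate_sweep if sweep else m.simulate_neutral)(params)
    genotypes = m.collapse_to_genotypes(m.pair_diploids(haps, seed=seed + 10_000))
    return m.scan(genotypes, sites, config)


neutral = [scan_one(seed) for seed in range(1, 21)]
sweep = scan_one(99, sweep=m.SweepModel(s=0.01, f=0.9))

normed = m.joint_normalize(sweep, neutral, mode="bins", n_bins=100)
top = normed.reindex(normed["std_score"].abs().sort_values(ascending=False).index)

print(f"{len(normed)} core sites scored; top |z| scores:")
print(top[["locus_id", "pos_bp", "freq_derived", "score", "std_score"]]
      .head(8).to_string(index=False))
print("\nThe sweep sits at 250 kbp: the largest |z| cluster around it, in")
print("both directions (hitchhiking low-frequency derived alleles sit on long")
print("homozygous-ancestral backgrounds and score negative). |z| > 2 marks a")
print("site as extreme in the window protocol.")
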