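# Methods

## Model and procedure

`mlgscan` detects recent positive selection from the decay of haplotype
homozygosity around a core site, computed on *multi-locus genotypes* (MLGs):
each diploid individual is represented by its per-site derived-allele count
in {0, 1, 2}, so no phase information is used.  The underlying assumptions
are the standard ones for EHH-family scans: biallelic sites with known
ancestral/derived orientation (the ALT allele is treated as derived), a
single chromosome per scan, complete genotypes (sites with missing calls are
dropped at load time), and a sample large enough that homozygous carriers of
the core allele exist.

For a core site `x0` and extension site `xi`, the sample is partitioned into
classes of identical MLG sequences over `x0..xi`.  Extending by one site can
only split classes, so the engine maintains the partition incrementally
(O(n) per site, JIT-compiled); the same partition yields full-sample EHH,
the core-conditioned `EHH_c`, and the complement `cEHH_c` because every
class is homogeneous at the core.  Curves are integrated into iHH with the
trapezoid rule over bp, cM, or per-site unit distances.  Unphased iHS/nSL
compare `iHH_c / ciHH_c` for the homozygous derived (c=2) and ancestral
(c=0) cores and keep the branch with the larger signed log10-ratio
(derived branch positive, ancestral branch negated; exact ties fall to the
ancestral branch — the two-branch rule applied literally).  XP statistics
compare full-sample iHH between populations A and B at common sites.
Log-ratios are computed as `log10(a) − log10(b)` so that population swaps
and core-allele recoding negate scores exactly in floating point.

Heterozygote-conditioned statistics (c=1) are never computed; a core is
skipped when either homozygous class is absent, when a needed iHH is zero,
or when a curve hits the chromosome edge without `trunc_ok`.

## Extension policy

| parameter | default | meaning |
|---|---|---|
| `cutoff` | 0.05 | stop extending once the tracked EHH values drop below this; the crossing point itself is kept, so the terminal trapezoid is not discarded |
| `max_gap_bp` | 200,000 | stop before crossing a larger inter-site gap |
| `max_extend_bp` | 1,000,000 | per-direction extension limit (bp/cM modes) |
| `max_extend_sites` | 100 | per-direction site budget (sites mode, i.e. nSL/XP-nSL) |
| `trunc_ok` | off | accept curves cut short by the chromosome edge |

For the unphased iHS walk, extension continues until `EHH_c` *and* `cEHH_c`
are both below the cutoff (per branch); for XP, until full-sample EHH is
below the cutoff in *both* populations, each population integrating its own
curve over the common extent.  Full-sample EHH at the core is
`Σ_c n_c²/n²` (below 1 at a polymorphic core), following the definition
rather than pinning it to 1.  Only the chromosome edge marks a curve as
truncated; gap and extension-limit stops do not.

## Standardization

iHS/nSL scores are z-scored within 1% derived-allele-frequency bins
(edges `[k/100, (k+1)/100)`, last bin closed at 1), XP statistics in a
single genome-wide bin.  Moments use the population (divide-by-N) standard
deviation; at the scale of a scan the difference from N−1 is negligible.
Bins with fewer than two scores, or zero spread, leave their records
unstandardized (NaN, flagged).  For simulation studies each replicate is
standardized *jointly*: moments come from the replicate pooled with the
neutral background, and only the replicate's scores are returned.

## Window protocol, power, false positive rate

Extreme scores cluster near sweeps, so calling operates on non-overlapping
100 kbp windows (half-open, 1-based bp): each window is summarized by the
proportion of scores with |z| > 2 (a one-sided `z > 2` mode exists for the
XP statistics, whose sweep signal is directional; two-sided is the default),
windows are ranked into 10 quantile bins by the number of scores they
contain, and the top 1% per bin (ceiling) is called, ties broken by larger
extreme count then stable order.

Power and FPR are replicate-level rates.  Each evaluated replicate is
pooled with the neutral background windows, the calling quota is applied,
and the replicate counts as detected when its focal window — the window
containing the sweep site, placed at the centre of the simulated region —
is called.  Replicates are evaluated one at a time against the neutral
windows; pooling all sweep replicates into a single call set would cap
power at the quota size regardless of signal strength.  For neutral
replicates the focal window is the region centre (where a sweep would sit);
counting *any* called window instead is available via `focal_pos_bp=None`,
but with five windows per 500 kbp replicate that reading inflates the
replicate-level rate roughly five-fold above the per-window calling
fraction and is not the default.

## Synthetic data

The generator produces structural mimics of population samples, not
coalescent-with-selection simulations.  Neutral backgrounds: the region is
split into independent linkage blocks (Poisson boundaries with intensity
`rho_like/2` over the region, i.e. mean block length `2L/rho_like`); each
block draws a Kingman coalescent genealogy and drops Poisson mutations on
branches proportional to length, giving the neutral site-frequency spectrum
within blocks, correlation between nearby sites, and independence across
blocks.  Defaults mirror a sample of 2n = 200 haplotypes from a population
of size N = 10,000 over L = 500 kbp with μ = 2.35e−8 and r = 1.2e−8 per
site per generation (`theta_like` = 4NμL = 470, `rho_like` = 4NrL = 240).

Sweeps are imposed on the neutral background: `round(f·n_hap)` carriers get
the derived allele at the core and copy a founder over a tract whose
per-side length is exponential with mean `s / (r·ln(4Ns))`, the classic
scaling of a hard sweep's haplotype footprint — stronger selection, longer
shared tracts.  Soft sweeps seed `ceil(e·n_hap)` founders; `g > 0` adds
`Poisson(μ·g·tract)` private flips per carrier to age a fixed sweep.  Two
population samples are drawn from one common background (shared site list)
with the sweep confined to one of them.

What this does *not* emulate: divergence/growth demographies, the
correlation structure of a true ancestral recombination graph across block
boundaries, background selection, allele-frequency trajectories of real
sweeps, or mutation/recombination-rate heterogeneity.  Passing tests
therefore certify the statistics' contracts (exactness of the partition
engine, sign conventions, invariances, and the ranking behaviour
sweep > neutral), not calibrated power on real demographies.

## Numerical and design choices

- All randomness flows through `numpy.random.default_rng(seed)`; every
  generator is reproducible from its seed alone, and the scan/norm/window
  pipeline is deterministic.
- Scores are written with six significant digits, which makes written files
  byte-stable under re-read/re-write.
- Phase destruction swaps the two alleles of each heterozygous cell with
  probability 0.5; since the unphased pipeline collapses to allele counts
  first, its outputs are bit-identical on scrambled data (tested, not
  assumed).
- Core-site MAF filter default 0.05; the filter only gates *cores* — all
  sites still extend haplotypes.  For XP scans the filter uses the target
  population's frequencies.
- Replicate-scale checks in the test suite use 500 neutral replicates at
  the full study geometry (100 diploids, 500 kbp) for the false positive
  rate and 100+100 replicates for the power direction; smaller 50 kbp /
  20-diploid fixtures cover the exact invariances.

## Known limitations

- Multi-allelic records and polyploid genotypes are out of scope (skipped
  with a warning at VCF load).
- The cM distance mode requires an external map; no gap-scaling of
  distances is applied.
- Windows are single-chromosome; no genome-wide stitching or FDR machinery
  beyond the top-1% rule.
- Unphased iHS/nSL need homozygous carriers of both alleles at the core, so
  small samples skip many low-frequency cores (visible in the README's
  worked example).
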