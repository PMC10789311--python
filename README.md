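# mlgscan

Haplotype-homozygosity selection scans — **iHS, nSL, XP-EHH, XP-nSL** — for
**unphased** diploid data, together with the classic phased versions, score
standardization, and a window-based sweep-calling protocol with power and
false-positive-rate estimation on synthetic replicates.

## Who this is for

Recent positive selection leaves long, high-frequency haplotypes and low
local diversity around the adaptive allele.  The EHH family of statistics
detects this decay of haplotype homozygosity with distance from a core site —
but classically requires phased haplotypes, which many non-model organisms
lack (no reference panels, no good recombination maps).  `mlgscan` computes
these statistics directly on *multi-locus genotypes*: each individual is
reduced to its per-site derived-allele count (0, 1 or 2), erasing phase
entirely.

## The statistics

For a sample of `n` diploids and a core site `x0`, let `C_xi` be the set of
distinct multi-locus genotype sequences spanning `x0..xi` and `n_h` the count
of type `h`:

    EHH(x_i)    = Σ_h n_h² / n²                      (full sample)
    EHH_c(x_i)  = Σ_{h ∈ H_c} n_h² / n_c²            (core genotype class c)
    cEHH_c(x_i) = Σ_{h ∉ H_c} n_h² / n_c′²           (complement)

Curves are integrated into iHH by the trapezoid rule over distance measured
in bp/cM (iHS, XP-EHH) or in number of sites (nSL, XP-nSL).  With the
homozygous ancestral (c=0) and homozygous derived (c=2) cores,

    iHS_2 = log10(iHH_2 / ciHH_2),   iHS_0 = log10(iHH_0 / ciHH_0)
    iHS   = iHS_2 if iHS_2 > iHS_0, else −iHS_0

so positive scores flag long low-diversity sequences around a homozygous
derived core.  Across two populations, `XP = log10(iHH_A / iHH_B)` on
full-sample EHH, positive when population A carries the longer haplotypes.
iHS/nSL are standardized within 1% derived-allele-frequency bins; XP
statistics genome-wide.  Because collapsing to allele counts commutes with
any re-assignment of alleles to haplotypes, the unphased statistics are
*bit-identical* on phased and phase-scrambled data.

## Worked example

```sh
mlgscan simulate --out rep1 --n-hap 40 --length 50000 --theta 47 --rho 24 --seed 3
mlgscan scan --nsl --unphased --trunc-ok --vcf rep1.vcf --maf 0.05 --out run1
mlgscan norm --files run1.nsl.unphased.out --bins 100
```

which prints

```
wrote rep1.vcf and rep1.map: 240 sites x 40 haplotypes
wrote run1.nsl.unphased.out: 27 scores, skipped {'maf_filter': 56, 'core_class_absent': 157}
wrote run1.nsl.unphased.out.norm: 19 standardized scores
```

`run1.nsl.unphased.out` holds one row per core site (locus, position,
derived frequency, the selected iHH numerator/denominator pair, and the
unstandardized log-ratio); the `.norm` file adds the within-frequency-bin
z-score and an extreme flag (|z| > 2).  Sites are skipped as cores when
their minor-allele frequency is below `--maf` or when one of the homozygous
core classes is absent — with only 20 diploids most low-frequency sites have
no homozygous-derived individual, which is why the single-population
statistics want large samples.  Records landing in frequency bins with fewer
than two scores stay unstandardized (flagged), hence 19 of 27.

The `examples/` directory has one narrative script per capability — EHH
decay around a sweep, a single-population unphased nSL scan, a
cross-population XP-nSL scan, and the full window-based power / FPR
protocol.  Each prints the numbers it computes and a line on what they mean:

```sh
python examples/04_power_fpr.py
# windows: 400
# power (sweep window called, s=0.01, f=0.9): 1.00
# false positive rate (neutral focal window): 0.03
```

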