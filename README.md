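# cloverscan

Selection scans **within a single generation**: detecting loci under
viability selection by comparing SNP allele frequencies between an
originally sown population and the survivors of replicate field plots.

The motivating setting is a perennial forage crop (red clover, an outbred
species with high within-cultivar diversity) sown in a replicated field
experiment: after 2–3 seasons only a fraction of plants survive, and the
survivor populations of each plot are genotyped (by GBS of individuals, or
by sequencing pooled DNA / pooled leaf tissue) and compared with the
original seed lot or with plots that received contrasting treatments (pure
stand vs species mixture, high vs low seeding density). Because mortality is
the only force acting — no reproduction, recombination or migration — a
simple per-locus frequency-shift test is valid, and replicate plots separate
consistent selection from drift and sampling error.

## The statistic

For each SNP and each comparison of two population samples with frequencies
q₁, q₂ of the same tracked allele:

* fixation index  **F_ST = (q₁ − q₂)² / (4 q̄ (1 − q̄))**, q̄ = (q₁+q₂)/2;
* chi-square test  **X² = 2N · F_ST** on 1 df, with 2N the summed count of
  successfully genotyped gametes of the two samples;
* a SNP is *selected at level P* only if **every** replicate comparison is
  individually significant at P (the intersection rule);
* the combined false-discovery-rate estimate for each level is
  **FDR = l · Pⁿ / d**, where l = loci tested, n = independent replicate
  comparisons, and d = loci passing the intersection;
* hits are optionally confirmed with a two-sided Fisher exact test on the
  pooled survivor vs original gamete counts.

Around that core the package provides GBS genotype QC (read-depth and
per-allele rules, per-population genotyping counts, MAF), allele-frequency
estimation from individuals and from pooled sequencing (ratio of summed
replicate-library counts), replicate-pool averaging and accuracy reports,
PCA views of populations and individuals, a balanced two-way treatment ANOVA
for candidate SNPs, and a forward simulator of the entire design (structured
base population, viability selection under heavy random mortality, GBS reads,
DNA/leaf pools) with ground truth for validation.

## Worked example

```python
import numpy as np
from cloverscan import (
    SimConfig, simulate_study1, FilterConfig, filter_genotype_calls,
    select_snps_individuals, frequencies_from_genotypes,
    SelectionScan, ScanConfig,
)

sim = simulate_study1(SimConfig(seed=11))          # 88 originals + 4 x 48 survivors
g = filter_genotype_calls(sim.genotypes, FilterConfig())
kept = select_snps_individuals(g, sim.populations, FilterConfig())
g = g.subset_snps([g.snp_ids.index(s.snp_id) for s in kept])
freqs = frequencies_from_genotypes(g, sim.populations)
result = SelectionScan(freqs, sim.populations, ScanConfig()).fit()
print(result.fdr_table())
```

prints

```
      P     l  n  d      fdr
0  0.10  1912  4  8  0.02390
1  0.05  1912  4  1  0.01195
2  0.01  1912  4  0      NaN
```

i.e. 1912 SNPs survived QC (l); 8 were significant in all four survivor
populations at P < 0.1, giving a combined FDR estimate of
1912 · 0.1⁴ / 8 ≈ 0.024 (NaN where no locus passed the intersection). `result.summary(0.05)` then
ranks the hits by mean absolute frequency shift with the original-population
frequency, the mean survivor frequency ± s.e., mean F_ST ± s.e. and the
Fisher-exact confirmation p per SNP. With the simulator's ground truth
(`sim.truth.selected_ids`) you can check which hits are planted loci.

The same model objects drive the treatment contrast
(`ScanConfig(comparison_mode="vs_opposite_group_mean")`, 8 comparisons with
n = 4 independent) and `TreatmentAnova(...).fit()` classifies candidate SNPs
by stand-type / seeding-density effects.

A thin CLI wraps the three analyses and the simulator:

```bash
cloverscan simulate --out sim/ --seed 7
cloverscan study1-scan --genotypes sim/study1_genotypes.tsv \
    --metadata sim/study1_meta.tsv --out scan/
cloverscan study3-scan --pools sim/study3_pools.tsv \
    --metadata sim/study3_meta.tsv --out scan/
```

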