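# Methods

## Setting and model

The pipeline analyses viability selection **within one generation**. A base
population (a synthetic outbred cultivar) is sown in replicate field plots;
after a period of heavy mortality the survivors of each plot are sampled and
genotyped. Because no reproduction, recombination or migration occurs, the
only evolutionary force moving allele frequencies inside a plot is
differential survival plus drift, so a per-locus two-sample frequency test
is a valid selection scan, and replicate plots discriminate consistent
selection from drift.

For two samples with frequencies q₁, q₂ of the same tracked allele the
fixation index is taken in its two-population variance form

    F_ST = (q₁ − q₂)² / (4 q̄ (1 − q̄)),   q̄ = (q₁ + q₂)/2,

which is algebraically identical to the between-population variance of q
over q̄(1−q̄) (the test suite verifies both forms agree to 1e-12).
Significance uses the classical X² = 2N·F_ST on one degree of freedom,
with 2N the summed genotyped-gamete count of the two samples — a biallelic
SNP yields a 2×2 allele-count table, hence df = 1. No continuity correction
is applied. Note that with the *unweighted* q̄ this statistic equals the
Pearson chi-square of the 2×2 table only for equal sample sizes; with
unequal sizes it is mildly anticonservative (about 0.06 realized per-test
level at nominal 0.05 for 176 vs 96 gametes). We keep the unweighted form
because the reported F_ST values are themselves unweighted.

A locus is declared selected at level P only when **all** replicate
comparisons are individually significant at P. The combined
false-discovery-rate estimate per level is FDR = l·Pⁿ/d (l loci tested,
n independent comparisons, d observed intersection hits). l counts only
SNPs testable in every comparison; with the stated QC filters the two
coincide. Selection is significance-only: consistency of the shift
direction across replicates is recorded but not required, so users can
filter on it downstream.

Two comparison designs are built in:

* **vs_original** — each survivor sample against the one original sample;
  n defaults to the number of survivor populations. Hits are confirmed by a
  two-sided Fisher exact test (sum of hypergeometric probabilities ≤ that of
  the observed table) of all survivors pooled against the original.
* **vs_opposite_group_mean** — each of 8 plots against the unweighted mean
  frequency of the opposite treatment group; all 8 tests must pass but
  n = 4 in the FDR because only four comparisons are independent. Each pool
  carries a nominal 2N of twice the pooled individuals (2×100 by default)
  and the group mean carries the sum of its plots' gamete counts; both are
  configurable because the effective sample size of a tissue pool is smaller
  than its nominal one.

### Known limitation: the FDR's independence assumption

The combined FDR treats the n replicate comparisons as independent. In the
vs_original design they are not: every comparison shares the same original
sample, whose sampling noise induces a correlation of
ρ = (1/2N_o)/(1/2N_o + 1/2N_s) between comparisons (≈ 0.35 at 176 vs 96
gametes). Normal-theory Monte Carlo and full simulation both show the null
intersection probability is then ~25× P⁴ at P = 0.1: about 5 expected null
hits per 2000 tested loci instead of 0.2, so l·Pⁿ/d can understate the true
false-discovery proportion by an order of magnitude at these sample sizes.
The acceptance suite documents this honestly: the FDR-consistency test under
the field design fails and is left failing, while a companion test shows the
formula is well calibrated when each comparison uses its own independent
reference sample. Practical consequences: treat reported FDRs as optimistic
lower bounds when one shared reference is used, prefer the Fisher
confirmation p-values for ranking, and consider genotyping a larger (or
split) reference sample to shrink ρ.

## QC rules

Genotype calls need ≥ `min_total_reads` (10) reads in total; heterozygotes
additionally need ≥ `min_reads_per_het_allele` (2) reads for each allele.
Failing calls are set missing, not demoted to homozygous — with a two-read
rule the evidence distinguishes poorly between a true homozygote and an
under-sampled heterozygote, and blanking is the conservative choice. SNPs
must be genotyped in ≥ `min_genotyped_per_pop` (25) individuals in *every*
population and have MAF strictly above 0.05 in the scoped population(s);
MAF is computed by gamete counting over non-missing calls, matching the 2N
bookkeeping of the test. Pooled data use inclusive read-depth windows
(10–126 per replicate library for DNA pools; 100–499 in all samples for
leaf pools) — per-library filtering masks failing pool×SNP cells before the
merge rather than vetoing the SNP. A chromosomal-only predicate drops
scaffold markers for map-based analyses.

## Frequency estimation

From genotypes: q = alt gametes / 2·genotyped, 2N = 2·genotyped. From
pools: replicate libraries are summed before the ratio (ratio of sums, not
mean of ratios — the two differ on skewed library depths). Frequencies are
polarised once per SNP to the minor allele of an anchor population (the
original, or the first sample) so the same allele is tracked everywhere;
per-population re-polarisation would corrupt cross-population differences.
Replicate tissue pools of one plot are averaged unweighted with NaN
replicates dropped. The pooled-vs-individual accuracy report stratifies
mean |q_pool − q_ind| and Pearson r² by merged pool depth over the standard
bins 10–49 … >599.

## Treatment ANOVA

Candidate SNPs are tested with a balanced two-way fixed-effects ANOVA
(stand type × seeding density, 2 replicate plots per cell, per-plot
frequencies as the response). The decomposition is computed from cell means
(type-I = type-III in the balanced case) with error df = N − 4; a constant
response returns p = 1 by convention; unbalanced layouts are rejected
explicitly rather than silently reweighted. The classification step
partitions candidates into stand-only / density-only / both / neither at
P < 0.05 per effect with no cross-SNP correction (candidate lists are short
and reported per SNP); star levels are the conventional 0.05/0.01/0.001.
The report also states the absolute mean frequency difference between the
two levels of each factor.

## PCA and the subpopulation split

Both PCA views use SNP-wise mean centring without unit-variance scaling
(scaling is available as a flag) and exact SVD, so results are
deterministic up to sign. Missing dosages are mean-imputed per SNP.
The minor-subpopulation summary splits PC1 scores with an exact
one-dimensional 2-means (threshold minimising within-cluster SSE — unlike a
randomised k-means this is deterministic and optimal in 1-D), and reports
the minor-cluster fraction per population.

## The simulator

`SimConfig` defaults describe one experiment: 2000 unlinked biallelic loci,
base frequencies uniform on (0.05, 0.95); a 0.17/0.83 two-subpopulation
mixture whose per-locus frequencies are Balding–Nichols perturbations with
parameter 2·F₀ so the realized pairwise fixation index between the
subpopulation frequency vectors averages F₀ = 0.02 (weak structure: leading
genotype-PCA components explain ~1–2% of variance, and the minor cluster is
recoverable from PC1). Genotypes are Hardy–Weinberg within subpopulation.

Each plot sows a cohort (2000 seeds; in the treatment design 7500/3750/
1875/938 by stand×density, following standard seed-rate arithmetic) of
which ~25% survive — survival fractions of this order are typical of dense
forage stands after 2–3 seasons. Twenty loci are under selection with
multiplicative fitness across loci: genotype survival weights
(1−s, 1−s/2, 1) with s on a grid 0.72–0.90 at base frequency 0.3, chosen so
the single-locus closed-form shifts span ≈ 0.15–0.26, the magnitude such
scans report. Survival is an independent Bernoulli thinning with
probabilities proportional to fitness, scaled (capped at 1, excess
redistributed) so the expected survivor count matches the target. For a
single locus this reproduces the closed form

    q' = (q² p₂ + q(1−q) p₁) / (q² p₂ + 2q(1−q) p₁ + (1−q)² p₀)

exactly (verified over 10³ plots). With many strongly selected loci the
total selection load saturates the survival probabilities: realized
per-locus shifts attenuate to roughly half their single-locus expectation
at 20 loci under 25% survival. This is real population genetics (soft
selection for a fixed number of survivor slots), not an artifact, and it is
why loci with realized shifts ≥ 0.2 only exist when few loci are under
strong selection; the power analysis uses a 4-locus configuration for that
reason. Treatment-specific loci (8 stand-type, 4 density) are active only
in matching plots.

Sequencing: GBS per-call depth is negative-binomial (mean 30, dispersion 3
— GBS depth is overdispersed relative to Poisson), alternate reads binomial
with symmetric error 10⁻³, and dosages are naively re-called (any mixed
support → heterozygote; zero depth → missing) so that the QC layer produces
realistic missingness. Pooled libraries share a per-locus gamma sequencing
propensity (restriction-site effect) with Poisson depths around mean·scale
(marginally negative-binomial, mean 250 for leaf pools, 60 per DNA-pool
library); leaf pools draw Dirichlet(1) tissue weights per replicate, which
at depth 250 yields replicate-to-replicate deviations of ~0.05 versus ~0.036
for equal-weight DNA pools — the observed contrast between the two pooling
strategies. Loci whose expected total depth exceeds 600 reads receive a
Beta(2, 5) contamination fraction of random allele balance, a
phenomenological stand-in for collapsed paralogs that reproduces the
U-shaped accuracy-vs-depth profile (accuracy degrades again above ~600
reads).

What the simulator does **not** model: linkage and LD (loci are
independent, so hitchhiking and the clustering of real hits are absent),
genotyping error beyond symmetric read error, locus-sharing of GBS depth
between individuals, multi-generation dynamics, and any environmental
correlation between plots. Passing tests therefore demonstrate the
statistical machinery under the design's assumptions, not robustness to
artifacts real GBS data may carry.

## Problem sizes and numerical choices

Simulation-based tests use 2000 loci, 4 plots of 2000 sown / 500 surviving /
48 sampled, and 88 originals — the design's own scale — with 10³ plot
replicates for the closed-form check and ≥10⁴ draws for estimator
calibration; these sizes give Monte-Carlo standard errors well below the
tested tolerances. Exact identities (ANOVA decomposition vs OLS projection,
Fisher vs hypergeometric enumeration, F_ST variance form) are asserted at
1e-10–1e-12. Degenerate inputs have defined conventions: monomorphic pairs
give NaN F_ST (excluded from l), zero-depth pools give NaN frequency,
constant ANOVA responses give p = 1, empty Fisher margins give p = 1, NaN
serialises as "NA". All randomness flows from a single integer seed; every
simulation is reproducible byte-for-byte.
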