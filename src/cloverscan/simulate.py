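"""Forward simulator for within-generation viability selection experiments.

The generator emulates the study design the scan assumes: an outbred base
population with weak two-subpopulation structure, replicate field plots each
sown with a cohort drawn from that base, heavy but mostly random mortality
with locus-specific viability selection at a handful of loci, and then
genotyping — either GBS reads on sampled individuals or pooled sequencing of
DNA pools / leaf pools.

Model summary
-------------
* Base allele frequencies are uniform on ``base_freq_range`` (minor allele
  above 0.05 by construction); the two subpopulations perturb them with a
  Balding–Nichols draw calibrated so the mean pairwise fixation index of the
  two frequency vectors is ~``divergence_fst``.
* Genotypes are Hardy–Weinberg within subpopulation; no linkage.
* Survival: each individual's fitness is the product over selected loci of a
  per-genotype survival probability ``(p0, p1, p2)``; survival is an
  independent Bernoulli draw with probabilities scaled so the expected
  survivor count equals ``n_survivors`` (every individual survives at most
  once). In the infinite-population limit a locus with pre-selection
  frequency q moves to

      q' = (q^2 p2 + q(1-q) p1) / (q^2 p2 + 2 q(1-q) p1 + (1-q)^2 p0).

* GBS reads: per-call depth is negative-binomial (overdispersed relative to
  Poisson), alternate reads binomial with a symmetric sequencing-error flip;
  dosages are re-called from the reads so the pipeline sees realistic
  missingness.
* Pools: individual contributions are equal (``dna_pool``) or
  Dirichlet-weighted (``leaf_pool``, modelling unequal tissue amounts);
  read counts are binomial at a negative-binomial depth. Above
  ``high_depth_cutoff`` reads a beta-distributed contamination fraction is
  mixed in — a phenomenological stand-in for paralog/repeat collapse that
  degrades very-high-depth markers.

All randomness flows from ``SimConfig.seed``; identical configs give
identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .datatypes import (
    GenotypeMatrix,
    PoolCountTable,
    PopulationMeta,
    SnpRecord,
)

#: sown seeds per plot for each (stand_type, seeding_density) treatment,
#: following typical seed-rate arithmetic for 7.5 m^2 plots.
SOWN_BY_TREATMENT = {
    ("pure", "high"): 7500,
    ("pure", "low"): 3750,
    ("mixed", "high"): 1875,
    ("mixed", "low"): 938,
}


@dataclass(frozen=True)
class SimConfig:
    """All simulator knobs, with the study conditions as defaults.

    The defaults describe one field experiment: 2000 biallelic loci of which
    20 are under selection (expected frequency shifts ~0.15-0.25), four
    replicate plots each sown with 2000 seeds of which 500 survive, 48
    survivors sampled per plot against 88 sampled originals, a 0.17/0.83
    subpopulation mixture at divergence 0.02, GBS depth mean 30, pooled
    sequencing depth mean 250 per library, and 100-individual leaf pools.
    """

    seed: int = 2019
    # loci
    n_loci: int = 2000
    n_selected: int = 20
    n_stand_loci: int = 8
    n_density_loci: int = 4
    selection_coeffs: tuple[float, ...] | None = None
    selected_base_freq: float = 0.3
    base_freq_range: tuple[float, float] = (0.05, 0.95)
    # structure
    minor_fraction: float = 0.17
    divergence_fst: float = 0.02
    # demography per plot
    n_sown: int = 2000
    n_survivors: int = 500
    n_plots: int = 4
    sample_n_survivor: int = 48
    sample_n_original: int = 88
    survival_fraction: float = 0.25  # used when sowing varies by treatment
    pool_individuals: int = 100
    # sequencing
    gbs_depth_mean: float = 30.0
    gbs_depth_dispersion: float = 3.0
    pool_depth_mean: float = 250.0
    pool_depth_dispersion: float = 8.0
    dna_library_depth_mean: float = 60.0
    seq_error: float = 0.001
    pool_concentration: float = 1.0
    high_depth_cutoff: int = 600
    high_depth_contamination: tuple[float, float] = (2.0, 5.0)

    def __post_init__(self) -> None:
        if not 0 <= self.minor_fraction <= 1:
            raise ValueError("minor_fraction must lie in [0, 1]")
        if self.n_survivors > self.n_sown:
            raise ValueError("n_survivors cannot exceed n_sown")
        if self.pool_concentration <= 0:
            raise ValueError("pool_concentration must be positive")
        if self.n_selected + self.n_stand_loci + self.n_density_loci > self.n_loci:
            raise ValueError("more selected loci than loci")

    def coeffs(self) -> np.ndarray:
        if self.selection_coeffs is not None:
            return np.asarray(self.selection_coeffs, dtype=float)
        if self.n_selected == 0:
            return np.zeros(0)
        return np.linspace(0.72, 0.90, self.n_selected)


@dataclass
class SimTruth:
    """Ground truth of one simulated experiment."""

    snps: list[SnpRecord]
    base_freq: np.ndarray  # (L,) alt-allele frequency of the mixed base
    subpop_freq: np.ndarray  # (2, L)
    selected_indices: np.ndarray  # loci selected in every plot
    stand_indices: np.ndarray  # selected only in pure-stand plots
    density_indices: np.ndarray  # selected only in high-density plots
    survival_probs: dict[int, tuple[float, float, float]]
    expected_post_freq: dict[int, float]  # infinite-population q' per locus
    depth_scale: np.ndarray | None = None  # per-SNP pooled-depth multiplier
    subpop_labels: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def selected_ids(self) -> list[str]:
        return [self.snps[j].snp_id for j in self.selected_indices]


def expected_post_selection_freq(
    q: float, probs: tuple[float, float, float]
) -> float:
    """Deterministic (infinite-population) post-viability-selection frequency.

    ``probs = (p0, p1, p2)`` are survival probabilities of the 0/1/2
    alt-dosage genotypes at Hardy–Weinberg proportions.
    """
    p0, p1, p2 = probs
    num = q * q * p2 + q * (1 - q) * p1
    den = q * q * p2 + 2 * q * (1 - q) * p1 + (1 - q) ** 2 * p0
    if den == 0:
        raise ValueError("all-zero survival weights")
    return num / den


def _expected_post_freq_structured(
    sub_q: np.ndarray, fractions: np.ndarray, probs: tuple[float, float, float]
) -> float:
    """Single-locus expectation for a subpopulation mixture.

    Each subpopulation is Hardy–Weinberg at its own frequency; selection
    reweights the pooled genotype distribution.
    """
    p0, p1, p2 = probs
    num = den = 0.0
    for f, q in zip(fractions, sub_q):
        num += f * (q * q * p2 + q * (1 - q) * p1)
        den += f * (q * q * p2 + 2 * q * (1 - q) * p1 + (1 - q) ** 2 * p0)
    return num / den


def _make_snps(L: int, rng: np.random.Generator) -> list[SnpRecord]:
    """Synthetic marker records: ~70% placed on chromosomes, rest scaffolds."""
    snps = []
    chrom_of = rng.integers(1, 8, size=L)
    on_chrom = rng.random(L) < 0.7
    pos = np.sort(rng.integers(1, 30_000_000, size=L))
    for j in range(L):
        if on_chrom[j]:
            snps.append(
                SnpRecord(f"S{j:05d}", f"Tp{chrom_of[j]}", int(pos[j]), "A", "G")
            )
        else:
            snps.append(SnpRecord(f"S{j:05d}", None, None, "A", "G"))
    return snps


def draw_truth(cfg: SimConfig, rng: np.random.Generator | None = None) -> SimTruth:
    """Base frequencies, structure and the selection regime for one experiment."""
    rng = rng or np.random.default_rng(cfg.seed)
    L = cfg.n_loci
    lo, hi = cfg.base_freq_range
    q = rng.uniform(lo, hi, size=L)
    n_sel_total = cfg.n_selected + cfg.n_stand_loci + cfg.n_density_loci
    chosen = rng.choice(L, size=n_sel_total, replace=False)
    sel = np.sort(chosen[: cfg.n_selected])
    stand = np.sort(chosen[cfg.n_selected: cfg.n_selected + cfg.n_stand_loci])
    dens = np.sort(chosen[cfg.n_selected + cfg.n_stand_loci:])
    q[chosen] = cfg.selected_base_freq
    # Balding-Nichols with F = 2 * divergence_fst: the expected pairwise
    # fixation index of two independent draws is F/2.
    if cfg.divergence_fst > 0:
        F = min(2 * cfg.divergence_fst, 0.999)
        a = q * (1 - F) / F
        b = (1 - q) * (1 - F) / F
        sub = np.stack([rng.beta(a, b), rng.beta(a, b)])
        sub = np.clip(sub, 1e-4, 1 - 1e-4)
    else:
        sub = np.stack([q, q])
    probs: dict[int, tuple[float, float, float]] = {}
    expected: dict[int, float] = {}
    all_sel = [(sel, cfg.coeffs())]
    if cfg.n_stand_loci:
        all_sel.append((stand, np.linspace(0.75, 0.9, cfg.n_stand_loci)))
    if cfg.n_density_loci:
        all_sel.append((dens, np.linspace(0.75, 0.9, cfg.n_density_loci)))
    fractions = np.array([1.0 - cfg.minor_fraction, cfg.minor_fraction])
    cohort_freq = fractions @ sub
    for indices, coeffs in all_sel:
        for j, s in zip(indices, coeffs):
            trip = (1.0 - s, 1.0 - s / 2.0, 1.0)
            probs[int(j)] = trip
            expected[int(j)] = _expected_post_freq_structured(sub[:, j], fractions, trip)
    # locus-specific sequencing propensity (restriction-site effect),
    # shared by every pooled library/sample of the experiment
    k_loc = cfg.pool_depth_dispersion
    depth_scale = rng.gamma(k_loc, 1.0 / k_loc, size=L)
    return SimTruth(
        snps=_make_snps(L, rng),
        base_freq=cohort_freq,
        subpop_freq=sub,
        selected_indices=sel,
        stand_indices=stand,
        density_indices=dens,
        survival_probs=probs,
        expected_post_freq=expected,
        depth_scale=depth_scale,
    )


def sample_cohort(
    truth: SimTruth,
    n: int,
    cfg: SimConfig,
    rng: np.random.Generator,
    population_id: str,
    id_prefix: str | None = None,
) -> GenotypeMatrix:
    """Draw ``n`` Hardy–Weinberg individuals from the structured base."""
    L = len(truth.snps)
    minor = rng.random(n) < cfg.minor_fraction
    dosage = np.empty((n, L), dtype=np.int8)
    for k, mask in ((0, ~minor), (1, minor)):
        cnt = int(mask.sum())
        if cnt:
            dosage[mask] = rng.binomial(2, truth.subpop_freq[k][None, :], size=(cnt, L))
    prefix = id_prefix or population_id
    individuals = [(f"{prefix}_{i:05d}", population_id) for i in range(n)]
    zeros = np.zeros((n, L), dtype=np.int32)
    g = GenotypeMatrix(list(truth.snps), individuals, dosage, zeros, zeros.copy())
    truth.subpop_labels[population_id] = minor.astype(int)
    return g


def simulate_base_population(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[GenotypeMatrix, SimTruth]:
    """One sown cohort of ``n_sown`` individuals plus the ground truth."""
    rng = rng or np.random.default_rng(cfg.seed)
    truth = draw_truth(cfg, rng)
    cohort = sample_cohort(truth, cfg.n_sown, cfg, rng, "base")
    return cohort, truth


def apply_viability_selection(
    cohort: GenotypeMatrix,
    cfg: SimConfig,
    rng: np.random.Generator,
    survival: Mapping[int, tuple[float, float, float]] | None = None,
    n_survivors: int | None = None,
    truth: SimTruth | None = None,
) -> GenotypeMatrix:
    """Thin a sown cohort to its survivors.

    Fitness is multiplicative over the selected loci (neutral loci
    contribute factor 1); survival is Bernoulli per individual with
    probabilities proportional to fitness, scaled (and capped at 1) so the
    expected survivor count is ``n_survivors``.
    """
    if survival is None:
        if truth is None:
            raise ValueError("pass survival probabilities or a SimTruth")
        survival = truth.survival_probs
    target = n_survivors if n_survivors is not None else cfg.n_survivors
    n = cohort.n_individuals
    w = np.ones(n)
    for j, trip in survival.items():
        w *= np.asarray(trip)[cohort.dosage[:, j]]
    total = w.sum()
    if total == 0:
        raise ValueError("all-zero survival weights")
    pi = w * (target / total)
    # cap at 1 and redistribute the excess over uncapped individuals
    for _ in range(100):
        over = pi > 1.0
        if not over.any():
            break
        excess = (pi[over] - 1.0).sum()
        pi[over] = 1.0
        free = ~over
        if pi[free].sum() == 0:
            break
        pi[free] *= 1.0 + excess / pi[free].sum()
    survive = rng.random(n) < np.minimum(pi, 1.0)
    return cohort.subset_individuals(np.flatnonzero(survive))


def simulate_gbs_reads(
    g: GenotypeMatrix, cfg: SimConfig, rng: np.random.Generator
) -> GenotypeMatrix:
    """Overlay negative-binomial GBS read depths and re-call dosages.

    Re-calling is deliberately naive (any mixed support -> heterozygote,
    zero depth -> missing); the QC layer then applies the depth rules, which
    is what produces realistic missingness downstream.
    """
    shape = g.dosage.shape
    k = cfg.gbs_depth_dispersion
    p = k / (k + cfg.gbs_depth_mean)
    depth = rng.negative_binomial(k, p, size=shape)
    f = g.dosage.astype(float) / 2.0
    f = f * (1 - cfg.seq_error) + (1 - f) * cfg.seq_error
    alt = rng.binomial(depth, np.where(g.dosage >= 0, f, 0.0))
    ref = depth - alt
    dosage = np.full(shape, -1, dtype=np.int8)
    dosage[(depth > 0) & (alt == 0)] = 0
    dosage[(depth > 0) & (alt == depth)] = 2
    dosage[(alt > 0) & (alt < depth)] = 1
    return GenotypeMatrix(
        list(g.snps), list(g.individuals), dosage,
        ref.astype(np.int32), alt.astype(np.int32),
    )


def simulate_pool_reads(
    g: GenotypeMatrix,
    cfg: SimConfig,
    mode: str = "dna_pool",
    n_replicates: int = 1,
    rng: np.random.Generator | None = None,
    pool_id: str = "pool",
    depth_mean: float | None = None,
    locus_scale: np.ndarray | None = None,
) -> PoolCountTable:
    """Pooled sequencing of one population sample.

    ``dna_pool``: every individual contributes equally (equal DNA amounts);
    ``leaf_pool``: contributions are Dirichlet(``pool_concentration``)
    weighted per replicate library, modelling unequal tissue amounts. Reads
    are binomial at a negative-binomial per-SNP depth; above
    ``high_depth_cutoff`` a beta contamination fraction corrupts the allele
    balance.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if mode not in ("dna_pool", "leaf_pool"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = rng or np.random.default_rng(cfg.seed)
    n, L = g.dosage.shape
    mean = depth_mean if depth_mean is not None else cfg.pool_depth_mean
    if locus_scale is None:
        # fresh locus effects: marginally negative-binomial depth
        k = cfg.pool_depth_dispersion
        locus_scale = rng.gamma(k, 1.0 / k, size=L)
    pop_id = g.individuals[0][1] if g.individuals else pool_id
    cref = np.zeros((n_replicates, L), dtype=np.int64)
    calt = np.zeros((n_replicates, L), dtype=np.int64)
    half_dos = g.dosage.astype(float) / 2.0
    # loci whose expected depth over the whole pooled experiment exceeds the
    # cutoff behave like collapsed paralogs/repeats: contaminated allele balance
    high = (mean * n_replicates * locus_scale) > cfg.high_depth_cutoff
    for r in range(n_replicates):
        if mode == "dna_pool":
            wts = np.full(n, 1.0 / n)
        else:
            wts = rng.dirichlet(np.full(n, cfg.pool_concentration))
        frac = wts @ half_dos
        frac = frac * (1 - cfg.seq_error) + (1 - frac) * cfg.seq_error
        depth = rng.poisson(mean * locus_scale)
        if high.any():
            a, b = cfg.high_depth_contamination
            contam = rng.beta(a, b, size=int(high.sum()))
            other = rng.uniform(0, 1, size=int(high.sum()))
            frac = frac.copy()
            frac[high] = (1 - contam) * frac[high] + contam * other
        alt = rng.binomial(depth, np.clip(frac, 0.0, 1.0))
        calt[r] = alt
        cref[r] = depth - alt
    pools = [(pool_id, pop_id, r) for r in range(n_replicates)]
    libs = [f"{pool_id}_lib{r}" for r in range(n_replicates)]
    return PoolCountTable(list(g.snps), pools, cref, calt, libs)


# ---------------------------------------------------------------------------
# full study designs
# ---------------------------------------------------------------------------

@dataclass
class Study1Data:
    genotypes: GenotypeMatrix  # originals + survivor samples, with GBS reads
    populations: list[PopulationMeta]
    truth: SimTruth


@dataclass
class Study3Data:
    pool_counts: PoolCountTable  # 12 leaf-pool samples (3 reps x 2 PsH plots)
    populations: list[PopulationMeta]
    groups: dict[str, str]  # pool_id -> plot id
    design: dict[str, tuple[str, str]]  # plot id -> (stand, density)
    truth: SimTruth


def _concat_genotypes(mats: Sequence[GenotypeMatrix]) -> GenotypeMatrix:
    return GenotypeMatrix(
        snps=list(mats[0].snps),
        individuals=[ind for m in mats for ind in m.individuals],
        dosage=np.concatenate([m.dosage for m in mats]),
        depth_ref=np.concatenate([m.depth_ref for m in mats]),
        depth_alt=np.concatenate([m.depth_alt for m in mats]),
    )


def simulate_study1(
    cfg: SimConfig, with_reads: bool = True, selection: bool = True
) -> Study1Data:
    """Original sample plus ``n_plots`` replicate survivor samples.

    With ``selection=False`` the experiment is fully neutral (mortality is
    random), which is the null configuration for calibration runs.
    """
    rng = np.random.default_rng(cfg.seed)
    truth = draw_truth(cfg, rng)
    survival = truth.survival_probs if selection else {}
    mats = [
        sample_cohort(truth, cfg.sample_n_original, cfg, rng, "orig")
    ]
    metas = [
        PopulationMeta("orig", "original", n_sampled=cfg.sample_n_original)
    ]
    # selection active in every plot: the shared loci only (study-1 design)
    shared = {j: survival[j] for j in truth.selected_indices if j in survival}
    for plot in range(1, cfg.n_plots + 1):
        pid = f"S{plot}"
        cohort = sample_cohort(truth, cfg.n_sown, cfg, rng, pid, id_prefix=f"{pid}c")
        survivors = apply_viability_selection(
            cohort, cfg, rng, survival=shared, n_survivors=cfg.n_survivors
        )
        take = rng.choice(
            survivors.n_individuals,
            size=min(cfg.sample_n_survivor, survivors.n_individuals),
            replace=False,
        )
        mats.append(survivors.subset_individuals(np.sort(take)))
        metas.append(
            PopulationMeta(
                pid, "survivor", stand_type="pure", seeding_density="high",
                harvest_regime="3H", replicate_plot=plot,
                n_sampled=len(take),
            )
        )
    g = _concat_genotypes(mats)
    if with_reads:
        g = simulate_gbs_reads(g, cfg, rng)
    return Study1Data(g, metas, truth)


def simulate_study2(
    cfg: SimConfig, n_libraries: int = 7
) -> tuple[GenotypeMatrix, PoolCountTable, SimTruth]:
    """An individually genotyped sample plus replicate DNA-pool libraries of
    the same individuals (the pooled-genotyping accuracy design)."""
    rng = np.random.default_rng(cfg.seed)
    truth = draw_truth(cfg, rng)
    sample = sample_cohort(truth, cfg.sample_n_original, cfg, rng, "orig")
    pools = simulate_pool_reads(
        sample, cfg, mode="dna_pool", n_replicates=n_libraries, rng=rng,
        pool_id="origpool", depth_mean=cfg.dna_library_depth_mean,
        locus_scale=truth.depth_scale,
    )
    reads = simulate_gbs_reads(sample, cfg, rng)
    return reads, pools, truth


def simulate_study3(cfg: SimConfig, selection: bool = True) -> Study3Data:
    """Eight survivor plots in a 2x2 treatment layout, leaf-pool genotyped.

    Selection regimes: the shared loci act in every plot, stand loci only in
    pure stands, density loci only at high seeding density. Pure-stand
    high-density plots get three replicate leaf pools each (fresh 100
    individuals and fresh tissue weights per replicate); other plots one.
    """
    rng = np.random.default_rng(cfg.seed)
    truth = draw_truth(cfg, rng)
    plots = []
    for stand in ("pure", "mixed"):
        for density in ("high", "low"):
            for rep in (1, 2):
                plots.append((stand, density, rep))
    tables = []
    metas = []
    groups: dict[str, str] = {}
    design: dict[str, tuple[str, str]] = {}
    for stand, density, rep in plots:
        plot_id = f"{'Ps' if stand == 'pure' else 'Ms'}{'H' if density == 'high' else 'L'}{rep}"
        n_sown = SOWN_BY_TREATMENT[(stand, density)]
        n_surv = max(int(round(cfg.survival_fraction * n_sown)), cfg.pool_individuals)
        cohort = sample_cohort(truth, n_sown, cfg, rng, plot_id, id_prefix=f"{plot_id}c")
        active: dict[int, tuple[float, float, float]] = {}
        if selection:
            active.update({int(j): truth.survival_probs[int(j)] for j in truth.selected_indices})
            if stand == "pure":
                active.update({int(j): truth.survival_probs[int(j)] for j in truth.stand_indices})
            if density == "high":
                active.update({int(j): truth.survival_probs[int(j)] for j in truth.density_indices})
        survivors = apply_viability_selection(
            cohort, cfg, rng, survival=active, n_survivors=n_surv
        )
        n_reps = 3 if (stand, density) == ("pure", "high") else 1
        for r in range(n_reps):
            take = rng.choice(
                survivors.n_individuals,
                size=min(cfg.pool_individuals, survivors.n_individuals),
                replace=False,
            )
            sample = survivors.subset_individuals(np.sort(take))
            pool_id = f"{plot_id}r{r + 1}" if n_reps > 1 else plot_id
            tables.append(
                simulate_pool_reads(
                    sample, cfg, mode="leaf_pool", n_replicates=1, rng=rng,
                    pool_id=pool_id, locus_scale=truth.depth_scale,
                )
            )
            groups[pool_id] = plot_id
        design[plot_id] = (stand, density)
        metas.append(
            PopulationMeta(
                plot_id, "survivor", stand_type=stand, seeding_density=density,
                harvest_regime="3H", replicate_plot=rep,
                n_sampled=cfg.pool_individuals,
            )
        )
    merged = PoolCountTable(
        snps=list(truth.snps),
        pools=[p for t in tables for p in t.pools],
        counts_ref=np.concatenate([t.counts_ref for t in tables]),
        counts_alt=np.concatenate([t.counts_alt for t in tables]),
        library_ids=[lib for t in tables for lib in t.library_ids],
    )
    # the pool population labels must reference the plot's PopulationMeta
    merged.pools = [(pid, groups[pid], rep) for (pid, _, rep) in merged.pools]
    return Study3Data(merged, metas, groups, design, truth)


def simulate_experiment(cfg: SimConfig, outdir) -> dict[str, str]:
    """Write a complete study-1/2/3 fixture set in the package's formats."""
    import os

    from . import io as cio

    os.makedirs(outdir, exist_ok=True)
    paths: dict[str, str] = {}

    s1 = simulate_study1(cfg)
    paths["study1_genotypes"] = os.path.join(outdir, "study1_genotypes.tsv")
    cio.write_genotypes_tsv(s1.genotypes, paths["study1_genotypes"])
    paths["study1_meta"] = os.path.join(outdir, "study1_meta.tsv")
    cio.write_population_meta(s1.populations, paths["study1_meta"])

    reads, pools, _ = simulate_study2(cfg)
    paths["study2_genotypes"] = os.path.join(outdir, "study2_genotypes.tsv")
    cio.write_genotypes_tsv(reads, paths["study2_genotypes"])
    paths["study2_pools"] = os.path.join(outdir, "study2_pools.tsv")
    cio.write_pool_counts(pools, paths["study2_pools"])

    s3 = simulate_study3(cfg)
    paths["study3_pools"] = os.path.join(outdir, "study3_pools.tsv")
    cio.write_pool_counts(s3.pool_counts, paths["study3_pools"])
    paths["study3_meta"] = os.path.join(outdir, "study3_meta.tsv")
    cio.write_population_meta(s3.populations, paths["study3_meta"])

    paths["truth"] = os.path.join(outdir, "truth.tsv")
    _write_truth(s1.truth, s3.truth, paths["truth"])
    return paths


def _write_truth(t1: SimTruth, t3: SimTruth, path) -> None:
    import pandas as pd

    rows = []
    for name, truth in (("study1", t1), ("study3", t3)):
        classes = (
            [("shared", j) for j in truth.selected_indices]
            + [("stand", j) for j in truth.stand_indices]
            + [("density", j) for j in truth.density_indices]
        )
        for cls, j in classes:
            j = int(j)
            p0, p1, p2 = truth.survival_probs[j]
            rows.append(
                {
                    "experiment": name,
                    "snp_id": truth.snps[j].snp_id,
                    "class": cls,
                    "base_freq": truth.base_freq[j],
                    "p0": p0, "p1": p1, "p2": p2,
                    "expected_post_freq": truth.expected_post_freq[j],
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")


__all__ = [
    "SimConfig",
    "SimTruth",
    "SOWN_BY_TREATMENT",
    "expected_post_selection_freq",
    "draw_truth",
    "sample_cohort",
    "simulate_base_population",
    "apply_viability_selection",
    "simulate_gbs_reads",
    "simulate_pool_reads",
    "simulate_study1",
    "simulate_study2",
    "simulate_study3",
    "simulate_experiment",
    "Study1Data",
    "Study3Data",
]
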