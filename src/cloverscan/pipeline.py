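"""End-to-end orchestration of the three analyses.

Each ``run_study*`` function reads inputs in the package's file dialects,
applies the QC appropriate to that design, runs the analysis, and writes the
artifacts. They are also callable with in-memory objects, which is how the
test-suite and the simulator exercise them.

* study 1 — individually genotyped original + replicate survivor samples:
  call filter -> SNP selection -> gamete-count frequencies -> intersection
  scan against the original -> combined FDR -> Fisher confirmation ->
  ranked report + PCA views.
* study 2 — individuals vs replicate DNA-pool libraries of the same sample:
  per-library depth window -> merge -> accuracy report by depth bin.
* study 3 — leaf-pool samples of a 2x2 treatment layout: all-samples window
  + chromosomal SNPs -> pool frequencies -> replicate averaging ->
  intersection scan against the opposite-group mean -> combined FDR ->
  two-way treatment ANOVA on candidates.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

from . import io as cio
from .anova import AnovaResult, TreatmentAnova
from .datatypes import FrequencyTable, GenotypeMatrix, PoolCountTable, PopulationMeta
from .filters import (
    FilterConfig,
    chromosomal_only,
    filter_genotype_calls,
    mask_pool_window,
    select_snps_individuals,
    select_snps_pools,
)
from .frequencies import (
    AccuracyReport,
    average_replicate_pools,
    compare_pool_vs_individual,
    frequencies_from_genotypes,
    frequencies_from_pools,
)
from .pca import genotype_pca, population_pca, plot_scores, subpopulation_proportion
from .scan import ScanConfig, ScanResult, SelectionScan

logger = logging.getLogger("cloverscan")


def _write_pca(pca, path) -> None:
    """Scores plus a variance-fraction footer row as TSV."""
    df = pca.to_frame()
    df.insert(0, "entity", df.index)
    df.loc["variance_fraction"] = ["variance_fraction", *pca.variance_fraction]
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


@dataclass
class PipelineConfig:
    """Paths plus the per-stage configurations for one pipeline run."""

    genotypes: str | None = None
    genotype_dialect: str = "tsv"
    pool_counts: str | None = None
    metadata: str | None = None
    candidates: str | None = None  # one SNP id per line (e.g. external outlier list)
    outdir: str = "."
    filter_config: FilterConfig = field(default_factory=FilterConfig)
    scan_config: ScanConfig = field(default_factory=ScanConfig)
    make_plots: bool = False


@dataclass
class Study1Artifacts:
    scan: ScanResult
    freqs: FrequencyTable
    n_snps_tested: int
    pca_populations: object
    pca_genotypes: object
    minor_cluster_fraction: dict[str, float]


def run_study1(
    cfg: PipelineConfig,
    genotypes: GenotypeMatrix | None = None,
    populations: list[PopulationMeta] | None = None,
) -> Study1Artifacts:
    """Survivors-vs-original intersection scan from individual genotypes."""
    g = genotypes if genotypes is not None else cio.read_genotypes(
        cfg.genotypes, cfg.genotype_dialect
    )
    pops = populations if populations is not None else cio.read_population_meta(cfg.metadata)
    n_survivor = sum(1 for p in pops if p.role == "survivor")
    if n_survivor < 2:
        raise ValueError("study 1 needs at least two survivor populations")
    g = filter_genotype_calls(g, cfg.filter_config)
    kept = select_snps_individuals(g, pops, cfg.filter_config)
    kept_idx = [g.snp_ids.index(s.snp_id) for s in kept]
    g = g.subset_snps(kept_idx)
    logger.info("study 1: %d SNPs pass QC", g.n_snps)
    freqs = frequencies_from_genotypes(g, pops, polarize="original")
    scan_cfg = cfg.scan_config
    if scan_cfg.comparison_mode != "vs_original":
        scan_cfg = ScanConfig(
            alpha_levels=scan_cfg.alpha_levels, comparison_mode="vs_original"
        )
    result = SelectionScan(freqs, pops, scan_cfg).fit()
    pca_pop = population_pca(freqs)
    pca_geno = genotype_pca(g)
    minor = subpopulation_proportion(pca_geno, g.individuals)
    os.makedirs(cfg.outdir, exist_ok=True)
    cio.write_scan_results(result, os.path.join(cfg.outdir, "study1_scan.tsv"))
    result.fdr_table().to_csv(
        os.path.join(cfg.outdir, "study1_fdr.tsv"), sep="\t", index=False, na_rep="NA"
    )
    result.summary().to_csv(
        os.path.join(cfg.outdir, "study1_report.tsv"), sep="\t", index=False,
        na_rep="NA", float_format="%.6g",
    )
    _write_pca(pca_pop, os.path.join(cfg.outdir, "study1_pca_populations.tsv"))
    _write_pca(pca_geno, os.path.join(cfg.outdir, "study1_pca_individuals.tsv"))
    if cfg.make_plots:
        plot_scores(pca_pop, os.path.join(cfg.outdir, "study1_pca_populations.png"))
        labels = dict(g.individuals)
        plot_scores(
            pca_geno, os.path.join(cfg.outdir, "study1_pca_individuals.png"),
            labels=labels,
        )
    return Study1Artifacts(result, freqs, g.n_snps, pca_pop, pca_geno, minor)


def run_study2(
    cfg: PipelineConfig,
    genotypes: GenotypeMatrix | None = None,
    pools: PoolCountTable | None = None,
) -> AccuracyReport:
    """Pooled-vs-individual allele-frequency accuracy by depth bin."""
    g = genotypes if genotypes is not None else cio.read_genotypes(
        cfg.genotypes, cfg.genotype_dialect
    )
    p = pools if pools is not None else cio.read_pool_counts(cfg.pool_counts)
    if not set(g.snp_ids) & set(p.snp_ids):
        raise ValueError("no SNPs shared between genotypes and pool counts")
    fc = cfg.filter_config
    g = filter_genotype_calls(g, fc)
    pop_id = g.individuals[0][1]
    meta = [PopulationMeta(pop_id, "original", n_sampled=g.n_individuals)]
    kept = select_snps_individuals(g, meta, FilterConfig(
        min_total_reads=fc.min_total_reads,
        min_reads_per_het_allele=fc.min_reads_per_het_allele,
        min_genotyped_per_pop=fc.min_genotyped_per_pop,
        maf_threshold=fc.maf_threshold,
        maf_scope="all_samples",
    ))
    keep_ids = [s.snp_id for s in kept if s.snp_id in set(p.snp_ids)]
    g = g.subset_snps([g.snp_ids.index(s) for s in keep_ids])
    p = p.subset_snps([p.snp_ids.index(s) for s in keep_ids])
    p = mask_pool_window(p, fc)  # per-library window, then merge
    f_ind = frequencies_from_genotypes(g, meta, polarize=None)
    f_pool = frequencies_from_pools(p, meta, merge="sum_replicate_libraries")
    merged_depth = p.depth.sum(axis=0)
    report = compare_pool_vs_individual(f_ind, f_pool, merged_depth)
    os.makedirs(cfg.outdir, exist_ok=True)
    report.to_tsv(os.path.join(cfg.outdir, "study2_accuracy.tsv"))
    return report


@dataclass
class Study3Artifacts:
    scan: ScanResult
    freqs: FrequencyTable  # per-plot, replicate-averaged
    anova: AnovaResult | None
    pca_samples: object


def run_study3(
    cfg: PipelineConfig,
    pools: PoolCountTable | None = None,
    populations: list[PopulationMeta] | None = None,
    groups: dict[str, str] | None = None,
    design: dict[str, tuple[str, str]] | None = None,
    candidates: list[str] | None = None,
) -> Study3Artifacts:
    """Treatment-contrast scan on leaf-pool samples plus candidate ANOVA."""
    p = pools if pools is not None else cio.read_pool_counts(cfg.pool_counts)
    pops = populations if populations is not None else cio.read_population_meta(cfg.metadata)
    if groups is None:
        groups = {pid: pop for pid, pop, _ in p.pools}
    if design is None:
        design = {
            m.population_id: (m.stand_type, m.seeding_density)
            for m in pops if m.role == "survivor"
        }
    if any(v[0] == "n/a" or v[1] == "n/a" for v in design.values()):
        raise ValueError("study 3 requires stand/density metadata for every plot")
    fc = cfg.filter_config
    kept = select_snps_pools(p, fc, scope="all_samples")
    kept = chromosomal_only(kept)
    idx = [p.snp_ids.index(s.snp_id) for s in kept]
    p = p.subset_snps(idx)
    logger.info("study 3: %d chromosomal SNPs pass the pooled QC", p.n_snps)
    f_samples = frequencies_from_pools(p, pops, merge="per_pool", polarize="first")
    # sample ids are library ids here; map them to their pool's plot
    lib_groups = {lib: groups[p.pools[i][0]] for i, lib in enumerate(p.library_ids)}
    f_plots = average_replicate_pools(f_samples, lib_groups)
    scan_cfg = cfg.scan_config
    if scan_cfg.comparison_mode != "vs_opposite_group_mean":
        scan_cfg = ScanConfig(
            alpha_levels=scan_cfg.alpha_levels,
            comparison_mode="vs_opposite_group_mean",
        )
    result = SelectionScan(f_plots, pops, scan_cfg).fit()
    anova_res = None
    cand = candidates
    if cand is None and cfg.candidates:
        with open(cfg.candidates) as fh:
            cand = [line.strip() for line in fh if line.strip()]
    if cand:
        cand = [c for c in cand if c in set(f_plots.snp_ids)]
        anova_res = TreatmentAnova(f_plots, design, cand).fit()
    else:
        logger.info("study 3: no candidate list; ANOVA stage skipped")
    pca_samples = population_pca(f_samples)
    os.makedirs(cfg.outdir, exist_ok=True)
    cio.write_scan_results(result, os.path.join(cfg.outdir, "study3_scan.tsv"))
    result.fdr_table().to_csv(
        os.path.join(cfg.outdir, "study3_fdr.tsv"), sep="\t", index=False, na_rep="NA"
    )
    if anova_res is not None:
        anova_res.to_tsv(os.path.join(cfg.outdir, "study3_anova.tsv"))
    _write_pca(pca_samples, os.path.join(cfg.outdir, "study3_pca_samples.tsv"))
    if cfg.make_plots:
        plot_scores(pca_samples, os.path.join(cfg.outdir, "study3_pca_samples.png"))
    return Study3Artifacts(result, f_plots, anova_res, pca_samples)


__all__ = [
    "PipelineConfig",
    "Study1Artifacts",
    "Study3Artifacts",
    "run_study1",
    "run_study2",
    "run_study3",
]
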