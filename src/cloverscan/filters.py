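"""Genotype- and SNP-level quality-control rules.

Two layers of QC are applied before any frequency is estimated:

* per-call: a genotype is kept only if it rests on at least
  ``min_total_reads`` reads in total and, for heterozygotes, at least
  ``min_reads_per_het_allele`` reads supporting *each* allele. Calls failing
  either rule are set missing (not demoted to homozygous).
* per-SNP: a SNP enters the analysis only if it is genotyped in at least
  ``min_genotyped_per_pop`` individuals in **every** population and its minor
  allele frequency exceeds ``maf_threshold`` (strict) in the scoped
  population(s). Pooled data use an inclusive read-depth window instead.

MAF is computed by gamete counting over non-missing calls
(``(2·hom_alt + het) / (2·genotyped)``), matching how ``2N`` is counted by
the downstream tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .datatypes import MISSING, GenotypeMatrix, PoolCountTable, PopulationMeta, SnpRecord


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for every inclusion rule, with the field-standard defaults.

    ``pool_depth_min``/``pool_depth_max`` form an inclusive window; typical
    settings are (10, 126) for per-library DNA-pool filtering and (100, 499)
    for leaf-pool samples.
    """

    min_total_reads: int = 10
    min_reads_per_het_allele: int = 2
    min_genotyped_per_pop: int = 25
    maf_threshold: float = 0.05
    maf_scope: str = "original_only"  # "original_only" | "all_samples"
    pool_depth_min: int = 10
    pool_depth_max: int = 126

    def __post_init__(self) -> None:
        for name in ("min_total_reads", "min_reads_per_het_allele",
                     "min_genotyped_per_pop", "pool_depth_min", "pool_depth_max"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.maf_threshold < 1:
            raise ValueError("maf_threshold must lie in [0, 1)")
        if self.maf_scope not in ("original_only", "all_samples"):
            raise ValueError(f"unknown maf_scope {self.maf_scope!r}")
        if self.pool_depth_min >= self.pool_depth_max:
            raise ValueError("pool_depth_min must be < pool_depth_max")


def filter_genotype_calls(g: GenotypeMatrix, cfg: FilterConfig = FilterConfig()) -> GenotypeMatrix:
    """Blank calls that fail the read-support rules; depths are kept.

    Total depth below ``min_total_reads`` blanks any call; a heterozygote
    additionally needs ``min_reads_per_het_allele`` reads for *each* allele.
    Homozygous calls are untouched by the per-allele rule. Pure
    transformation: returns a new matrix.
    """
    out = g.copy()
    total = out.depth_ref.astype(np.int64) + out.depth_alt
    low_total = total < cfg.min_total_reads
    het = out.dosage == 1
    het_fail = het & (
        (out.depth_ref < cfg.min_reads_per_het_allele)
        | (out.depth_alt < cfg.min_reads_per_het_allele)
    )
    out.dosage[low_total | het_fail] = MISSING
    return out


def _gamete_counts(g: GenotypeMatrix, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(alt gametes, total gametes) per SNP over the masked individuals."""
    dos = g.dosage[mask]
    called = dos != MISSING
    alt = np.where(called, dos, 0).sum(axis=0, dtype=np.int64)
    return alt, 2 * called.sum(axis=0, dtype=np.int64)


def minor_allele_frequency(g: GenotypeMatrix, mask: np.ndarray | None = None) -> np.ndarray:
    """Per-SNP MAF by gamete counting over non-missing calls (NaN if none)."""
    if mask is None:
        mask = np.ones(g.n_individuals, dtype=bool)
    alt, tot = _gamete_counts(g, mask)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(tot > 0, alt / np.maximum(tot, 1), np.nan)
    return np.minimum(f, 1.0 - f)


def select_snps_individuals(
    g: GenotypeMatrix,
    pops: Sequence[PopulationMeta],
    cfg: FilterConfig = FilterConfig(),
) -> list[SnpRecord]:
    """SNPs genotyped in >= ``min_genotyped_per_pop`` individuals of every
    population, with MAF strictly above ``maf_threshold`` in the scoped
    population(s). ``g`` should already be call-filtered."""
    masks = {}
    for p in pops:
        m = g.population_mask(p.population_id)
        if not m.any():
            raise ValueError(f"population {p.population_id!r} has no individuals in the matrix")
        masks[p.population_id] = m
    called = g.dosage != MISSING
    keep = np.ones(g.n_snps, dtype=bool)
    for m in masks.values():
        keep &= called[m].sum(axis=0) >= cfg.min_genotyped_per_pop
    if cfg.maf_scope == "original_only":
        scope_masks = [masks[p.population_id] for p in pops if p.role == "original"]
        if not scope_masks:
            raise ValueError("maf_scope 'original_only' requires an original population")
    else:
        scope_masks = [np.ones(g.n_individuals, dtype=bool)]
    for m in scope_masks:
        maf = minor_allele_frequency(g, m)
        keep &= np.nan_to_num(maf, nan=0.0) > cfg.maf_threshold
    return [g.snps[j] for j in np.flatnonzero(keep)]


def mask_pool_window(p: PoolCountTable, cfg: FilterConfig) -> PoolCountTable:
    """Zero out pool x SNP cells whose depth falls outside the inclusive
    window, so they contribute no reads when libraries are merged."""
    depth = p.depth
    bad = (depth < cfg.pool_depth_min) | (depth > cfg.pool_depth_max)
    out = PoolCountTable(
        snps=list(p.snps),
        pools=list(p.pools),
        counts_ref=np.where(bad, 0, p.counts_ref),
        counts_alt=np.where(bad, 0, p.counts_alt),
        library_ids=list(p.library_ids),
    )
    return out


def select_snps_pools(
    p: PoolCountTable,
    cfg: FilterConfig = FilterConfig(),
    scope: str = "per_library",
) -> list[SnpRecord]:
    """SNPs surviving the pooled-data depth window.

    scope:
      * ``per_library`` — the window is applied within each replicate
        library; a SNP survives if at least one library passes (failing
        cells are dropped before merging, see :func:`mask_pool_window`).
      * ``after_merge`` — the window applies to depth summed over libraries
        of each pool.
      * ``all_samples`` — the window *and* the MAF rule must hold in every
        pool sample.
    """
    depth = p.depth
    in_window = (depth >= cfg.pool_depth_min) & (depth <= cfg.pool_depth_max)
    if scope == "per_library":
        keep = in_window.any(axis=0)
    elif scope == "after_merge":
        pool_ids = [pid for pid, _, _ in p.pools]
        merged = {}
        for i, pid in enumerate(pool_ids):
            merged[pid] = merged.get(pid, 0) + depth[i]
        keep = np.ones(p.n_snps, dtype=bool)
        for d in merged.values():
            keep &= (d >= cfg.pool_depth_min) & (d <= cfg.pool_depth_max)
    elif scope == "all_samples":
        keep = in_window.all(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(depth > 0, p.counts_alt / np.maximum(depth, 1), np.nan)
        maf = np.minimum(f, 1.0 - f)
        keep &= np.nan_to_num(maf, nan=0.0).min(axis=0) > cfg.maf_threshold
        keep &= ~np.isnan(maf).any(axis=0)
    else:
        raise ValueError(f"unknown scope {scope!r}")
    return [p.snps[j] for j in np.flatnonzero(keep)]


def chromosomal_only(snps: Sequence[SnpRecord]) -> list[SnpRecord]:
    """Drop SNPs not placed on a chromosome (scaffold/unmapped tags)."""
    return [s for s in snps if s.is_chromosomal]


__all__ = [
    "FilterConfig",
    "filter_genotype_calls",
    "select_snps_individuals",
    "select_snps_pools",
    "mask_pool_window",
    "minor_allele_frequency",
    "chromosomal_only",
]
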