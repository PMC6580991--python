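"""Allele-frequency estimation from genotypes and from pooled read counts.

From individual genotypes the frequency of a SNP in a population is the
gamete-count ratio ``(2·hom_alt + het) / (2·genotyped)`` with
``2N = 2·genotyped`` recorded alongside. From pooled samples it is the read
ratio ``alt / (ref + alt)`` after summing counts over a pool's replicate
libraries (ratio of sums, not mean of ratios), with a *nominal* gamete count
of twice the number of pooled individuals.

Frequencies are polarised once per SNP to a fixed tracked allele — the minor
allele of a chosen anchor population — so that the same allele is followed in
every population and cross-population differences are directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    MISSING,
    FrequencyTable,
    GenotypeMatrix,
    PoolCountTable,
    PopulationMeta,
)

#: Read-depth bins used for pooled-vs-individual accuracy reports.
DEFAULT_DEPTH_BINS: list[tuple[int, float]] = [
    (10, 49), (50, 99), (100, 149), (150, 199), (200, 299),
    (300, 399), (400, 499), (500, 599), (600, float("inf")),
]


def _polarize(f: FrequencyTable, anchor_row: int) -> FrequencyTable:
    """Track the minor allele of the anchor population at every SNP."""
    anchor_q = f.q[anchor_row]
    flip = anchor_q > 0.5  # NaN anchors stay alt-tracked
    flip = np.where(np.isnan(anchor_q), False, flip)
    q = np.where(flip[None, :], 1.0 - f.q, f.q)
    return FrequencyTable(f.snps, f.populations, q, f.two_n, ~flip)


def frequencies_from_genotypes(
    g: GenotypeMatrix,
    pops: Sequence[PopulationMeta],
    polarize: str | None = "original",
) -> FrequencyTable:
    """Per-population allele frequencies by gamete counting.

    ``polarize``: ``"original"`` tracks the minor allele of the population
    whose role is ``original``; ``"first"`` anchors on the first listed
    population; ``None`` tracks the alternate allele as called.
    """
    pop_ids = [p.population_id for p in pops]
    q = np.full((len(pops), g.n_snps), np.nan)
    two_n = np.zeros((len(pops), g.n_snps), dtype=np.int64)
    for k, p in enumerate(pops):
        mask = g.population_mask(p.population_id)
        if not mask.any():
            raise ValueError(f"population {p.population_id!r} absent from genotype matrix")
        dos = g.dosage[mask]
        called = dos != MISSING
        alt = np.where(called, dos, 0).sum(axis=0, dtype=np.int64)
        tn = 2 * called.sum(axis=0, dtype=np.int64)
        with np.errstate(invalid="ignore", divide="ignore"):
            q[k] = np.where(tn > 0, alt / np.maximum(tn, 1), np.nan)
        two_n[k] = tn
    f = FrequencyTable(list(g.snps), pop_ids, q, two_n)
    if polarize is None:
        return f
    if polarize == "original":
        anchors = [k for k, p in enumerate(pops) if p.role == "original"]
        anchor = anchors[0] if anchors else 0
    elif polarize == "first":
        anchor = 0
    else:
        raise ValueError(f"unknown polarize mode {polarize!r}")
    return _polarize(f, anchor)


def frequencies_from_pools(
    p: PoolCountTable,
    pops: Sequence[PopulationMeta] | None = None,
    merge: str = "sum_replicate_libraries",
    nominal_n: int = 100,
    polarize: str | None = None,
) -> FrequencyTable:
    """Allele frequencies from pooled read counts.

    With ``merge="sum_replicate_libraries"`` counts are summed over the
    replicate libraries of each pool before the ratio is taken; with
    ``"per_pool"`` every library row yields its own sample. ``two_n`` is the
    nominal gamete count ``2 × n_sampled`` from the population metadata
    (falling back to ``2 × nominal_n``); the true effective sample size of a
    pool is smaller, so treat it as an upper bound.
    """
    if merge == "sum_replicate_libraries":
        order: dict[str, list[int]] = {}
        for i, (pid, _, _) in enumerate(p.pools):
            order.setdefault(pid, []).append(i)
        sample_ids = list(order)
        cref = np.stack([p.counts_ref[rows].sum(axis=0) for rows in order.values()])
        calt = np.stack([p.counts_alt[rows].sum(axis=0) for rows in order.values()])
        sample_pop = {pid: p.pools[rows[0]][1] for pid, rows in order.items()}
    elif merge == "per_pool":
        sample_ids = list(p.library_ids)
        cref, calt = p.counts_ref, p.counts_alt
        sample_pop = {lid: p.pools[i][1] for i, lid in enumerate(p.library_ids)}
    else:
        raise ValueError(f"unknown merge mode {merge!r}")
    depth = cref + calt
    with np.errstate(invalid="ignore", divide="ignore"):
        q = np.where(depth > 0, calt / np.maximum(depth, 1), np.nan)
    n_by_pop = {m.population_id: m.n_sampled for m in pops or []}
    two_n = np.stack(
        [
            np.full(p.n_snps, 2 * n_by_pop.get(sample_pop[sid], nominal_n), dtype=np.int64)
            for sid in sample_ids
        ]
    )
    f = FrequencyTable(list(p.snps), sample_ids, q, two_n)
    if polarize == "first":
        f = _polarize(f, 0)
    elif polarize is not None:
        raise ValueError(f"unknown polarize mode {polarize!r}")
    return f


def average_replicate_pools(
    f: FrequencyTable, groups: Mapping[str, str]
) -> FrequencyTable:
    """Average replicate pool samples of the same plot (unweighted mean).

    ``groups`` maps every sample id in ``f`` to a plot id; NaN replicates are
    excluded from the mean (a plot with all-NaN replicates stays NaN).
    """
    unmapped = [s for s in f.populations if s not in groups]
    if unmapped:
        raise ValueError(f"pools without a plot mapping: {unmapped}")
    plot_rows: dict[str, list[int]] = {}
    for k, sid in enumerate(f.populations):
        plot_rows.setdefault(groups[sid], []).append(k)
    plots = list(plot_rows)
    q = np.full((len(plots), f.n_snps), np.nan)
    two_n = np.zeros((len(plots), f.n_snps), dtype=np.int64)
    import warnings

    for r, plot in enumerate(plots):
        rows = plot_rows[plot]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN plots
            q[r] = np.nanmean(f.q[rows], axis=0)
        two_n[r] = f.two_n[rows].max(axis=0)
    return FrequencyTable(list(f.snps), plots, q, two_n, f.tracked_is_alt.copy())


@dataclass
class AccuracyReport:
    """Pooled-vs-individual frequency accuracy, stratified by pool depth.

    Per inclusive depth bin: number of SNPs, mean absolute deviation
    ``|q_pool − q_ind|`` and squared Pearson correlation of the two
    frequency vectors (NaN when fewer than two SNPs fall in the bin).
    """

    depth_bins: list[tuple[int, float]]
    n_snps: np.ndarray
    mean_abs_deviation: np.ndarray
    r_squared: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        labels = [
            f"{lo}-{int(hi)}" if np.isfinite(hi) else f">{lo - 1}"
            for lo, hi in self.depth_bins
        ]
        return pd.DataFrame(
            {
                "reads": labels,
                "n_snps": self.n_snps,
                "mean_abs_deviation": self.mean_abs_deviation,
                "r_squared": self.r_squared,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.4g")


def compare_pool_vs_individual(
    f_ind: FrequencyTable,
    f_pool: FrequencyTable,
    pool_depth: np.ndarray,
    bins: Sequence[tuple[int, float]] | None = None,
    ind_population: str | None = None,
    pool_population: str | None = None,
) -> AccuracyReport:
    """Accuracy of pool-based frequencies against individual-based ones.

    Both tables must cover the same SNP list in the same order;
    ``pool_depth`` is the merged read depth per SNP used for binning.
    """
    if f_ind.snp_ids != f_pool.snp_ids:
        raise ValueError("frequency tables cover different SNP universes")
    bins = list(bins) if bins is not None else list(DEFAULT_DEPTH_BINS)
    qi = f_ind.row(ind_population) if ind_population else f_ind.q[0]
    qp = f_pool.row(pool_population) if pool_population else f_pool.q[0]
    # compare on a common tracked allele
    if not np.array_equal(f_ind.tracked_is_alt, f_pool.tracked_is_alt):
        qp = np.where(f_ind.tracked_is_alt != f_pool.tracked_is_alt, 1.0 - qp, qp)
    pool_depth = np.asarray(pool_depth)
    ok = np.isfinite(qi) & np.isfinite(qp)
    n, dev, r2 = [], [], []
    for lo, hi in bins:
        sel = ok & (pool_depth >= lo) & (pool_depth <= hi)
        m = int(sel.sum())
        n.append(m)
        dev.append(float(np.abs(qp[sel] - qi[sel]).mean()) if m else np.nan)
        if m >= 2 and np.std(qi[sel]) > 0 and np.std(qp[sel]) > 0:
            r2.append(float(np.corrcoef(qi[sel], qp[sel])[0, 1] ** 2))
        else:
            r2.append(np.nan)
    return AccuracyReport(bins, np.array(n), np.array(dev), np.array(r2))


__all__ = [
    "DEFAULT_DEPTH_BINS",
    "AccuracyReport",
    "frequencies_from_genotypes",
    "frequencies_from_pools",
    "average_replicate_pools",
    "compare_pool_vs_individual",
]
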