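"""Principal-component views of allele frequencies and genotypes.

Two uses: (a) population-level PCA of per-SNP frequencies to visualise how
survivor populations diverge from each other and from the sown population,
and (b) individual-level PCA of genotype dosages to visualise population
structure (here, a weak two-subpopulation mixture). Matrices are SNP-wise
mean-centred; unit-variance scaling is off by default. Missing dosages are
mean-imputed per SNP. Decomposition is by singular values of the centred
matrix, so scores are exact and deterministic (up to sign).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import MISSING, FrequencyTable, GenotypeMatrix


@dataclass
class PcaResult:
    """Scores (entities x components), per-component variance fractions, and
    optionally the SNP loadings."""

    entity_ids: list[str]
    scores: np.ndarray
    variance_fraction: np.ndarray
    loadings: np.ndarray | None = None

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]

    def to_frame(self):
        import pandas as pd

        cols = {f"PC{i+1}": self.scores[:, i] for i in range(self.n_components)}
        return pd.DataFrame(cols, index=self.entity_ids)


def _pca(matrix: np.ndarray, ids: list[str], n_components: int | None,
         scale: bool, keep_loadings: bool) -> PcaResult:
    x = matrix - matrix.mean(axis=0, keepdims=True)
    if scale:
        sd = x.std(axis=0, ddof=0)
        x = x / np.where(sd > 0, sd, 1.0)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    total = float((s**2).sum())
    k = min(n_components or len(s), len(s))
    var_frac = (s[:k] ** 2) / total if total > 0 else np.zeros(k)
    return PcaResult(
        entity_ids=ids,
        scores=u[:, :k] * s[:k],
        variance_fraction=var_frac,
        loadings=vt[:k].T if keep_loadings else None,
    )


def population_pca(
    f: FrequencyTable,
    n_components: int | None = 3,
    scale: bool = False,
    keep_loadings: bool = False,
) -> PcaResult:
    """PCA of the populations x SNPs frequency matrix.

    SNPs with any missing frequency are dropped; columns are mean-centred
    over populations. With k populations at most k-1 informative components
    exist; ``n_components`` is truncated accordingly.
    """
    if len(f.populations) < 2:
        raise ValueError("population PCA needs at least two populations")
    ok = np.isfinite(f.q).all(axis=0)
    return _pca(f.q[:, ok], list(f.populations), n_components, scale, keep_loadings)


def genotype_pca(
    g: GenotypeMatrix,
    n_components: int | None = 10,
    scale: bool = False,
    keep_loadings: bool = False,
) -> PcaResult:
    """PCA of individuals x SNPs dosages, mean-imputing missing calls per SNP.

    SNPs with no calls at all are dropped.
    """
    x = g.dosage.astype(float)
    x[g.dosage == MISSING] = np.nan
    col_mean = np.nanmean(np.where(np.isnan(x), np.nan, x), axis=0)
    keep = np.isfinite(col_mean)
    x = x[:, keep]
    col_mean = col_mean[keep]
    idx = np.where(np.isnan(x))
    x[idx] = col_mean[idx[1]]
    return _pca(x, [i for i, _ in g.individuals], n_components, scale, keep_loadings)


def kmeans_1d_two(values: np.ndarray) -> np.ndarray:
    """Exact two-cluster 1-D k-means: the optimal split is a threshold
    between consecutive sorted values minimising within-cluster SSE.
    Returns 0/1 labels (0 = lower cluster)."""
    v = np.asarray(values, dtype=float)
    order = np.argsort(v, kind="mergesort")
    sv = v[order]
    n = len(sv)
    csum = np.cumsum(sv)
    csq = np.cumsum(sv**2)
    best_sse, best_k = np.inf, 1
    for k in range(1, n):  # lower cluster = first k sorted values
        s1, q1 = csum[k - 1], csq[k - 1]
        s2, q2 = csum[-1] - s1, csq[-1] - q1
        sse = (q1 - s1**2 / k) + (q2 - s2**2 / (n - k))
        if sse < best_sse - 1e-15:
            best_sse, best_k = sse, k
    labels = np.zeros(n, dtype=int)
    labels[order[best_k:]] = 1
    return labels


def subpopulation_proportion(
    pca: PcaResult,
    individuals: list[tuple[str, str]],
) -> dict[str, float]:
    """Per-population fraction of individuals in the minor PC1 cluster.

    Individuals are split into two clusters by exact 1-D 2-means on their
    PC1 scores (sign-invariant); the minor cluster is the smaller one
    overall. Returns NaN for every population when PC1 is degenerate
    (zero variance).
    """
    ids = {ind: pop for ind, pop in individuals}
    pops: dict[str, list[int]] = {}
    for i, ent in enumerate(pca.entity_ids):
        pops.setdefault(ids[ent], []).append(i)
    pc1 = pca.scores[:, 0]
    if np.std(pc1) == 0:
        return {pop: float("nan") for pop in pops}
    labels = kmeans_1d_two(pc1)
    minor = 1 if (labels == 1).sum() < (labels == 0).sum() else 0
    return {
        pop: float(np.mean(labels[rows] == minor)) for pop, rows in pops.items()
    }


def plot_scores(
    pca: PcaResult,
    path,
    components: tuple[int, int] = (0, 1),
    labels: dict[str, str] | None = None,
) -> None:
    """Scatter plot of two PCs, coloured by an entity -> group mapping."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    a, b = components
    fig, ax = plt.subplots(figsize=(5, 4))
    groups = sorted({(labels or {}).get(e, "all") for e in pca.entity_ids})
    for grp in groups:
        rows = [i for i, e in enumerate(pca.entity_ids)
                if (labels or {}).get(e, "all") == grp]
        ax.scatter(pca.scores[rows, a], pca.scores[rows, b], s=12, label=grp)
    ax.set_xlabel(f"PC{a+1} ({100 * pca.variance_fraction[a]:.1f}%)")
    ax.set_ylabel(f"PC{b+1} ({100 * pca.variance_fraction[b]:.1f}%)")
    if len(groups) > 1:
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


__all__ = [
    "PcaResult",
    "population_pca",
    "genotype_pca",
    "subpopulation_proportion",
    "kmeans_1d_two",
    "plot_scores",
]
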