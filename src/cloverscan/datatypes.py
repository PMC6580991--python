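"""Core in-memory containers shared by every pipeline stage.

The pipeline moves data through four table shapes:

* :class:`GenotypeMatrix` — individuals x SNPs diploid dosage calls (count of
  the alternate allele, 0/1/2, ``MISSING`` for no call) together with the
  per-allele read depths they were called from.
* :class:`PoolCountTable` — pooled-sample libraries x SNPs reference/alternate
  read counts, with replicate-library provenance.
* :class:`FrequencyTable` — populations x SNPs frequency ``q`` of one fixed
  tracked allele per SNP, plus the genotyped-gamete count ``2N`` per cell.
* Per-SNP scan output lives in :class:`cloverscan.scan.ScanResult`.

All matrices are oriented rows = entities (individuals / pools / populations),
columns = SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: Sentinel for a missing dosage call in :class:`GenotypeMatrix.dosage`.
MISSING: int = -1

_STAND_TYPES = {"pure", "mixed", "n/a"}
_DENSITIES = {"high", "low", "n/a"}
_HARVESTS = {"3H", "5H", "n/a"}
_ROLES = {"original", "survivor"}


@dataclass(frozen=True)
class SnpRecord:
    """A biallelic SNP.

    ``snp_id`` is either a sequencing-tag name (``TP24824``) or a positional
    label (``Tp3_5909984``); ``chromosome``/``position`` are filled when the
    marker has been mapped (1-based coordinates), else ``None`` (scaffold or
    unmapped tag).
    """

    snp_id: str
    chromosome: str | None = None
    position: int | None = None
    ref_allele: str = "A"
    alt_allele: str = "G"

    def __post_init__(self) -> None:
        if self.chromosome is not None and self.position is not None:
            if self.position < 1:
                raise ValueError(f"position must be >= 1, got {self.position}")

    @property
    def is_chromosomal(self) -> bool:
        """True when the SNP is placed on a chromosome (not a scaffold)."""
        return self.chromosome is not None


@dataclass(frozen=True)
class PopulationMeta:
    """Metadata for one population sample (a field plot or the sown seed lot).

    The original (sown) population carries no field treatment, so its
    treatment fields must all be ``"n/a"``.
    """

    population_id: str
    role: str  # "original" | "survivor"
    stand_type: str = "n/a"  # "pure" | "mixed" | "n/a"
    seeding_density: str = "n/a"  # "high" | "low" | "n/a"
    harvest_regime: str = "n/a"  # "3H" | "5H" | "n/a"
    replicate_plot: int = 0
    n_sampled: int = 1

    def __post_init__(self) -> None:
        if self.role not in _ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        if self.stand_type not in _STAND_TYPES:
            raise ValueError(f"unknown stand_type {self.stand_type!r}")
        if self.seeding_density not in _DENSITIES:
            raise ValueError(f"unknown seeding_density {self.seeding_density!r}")
        if self.harvest_regime not in _HARVESTS:
            raise ValueError(f"unknown harvest_regime {self.harvest_regime!r}")
        if self.n_sampled <= 0:
            raise ValueError("n_sampled must be positive")
        if self.role == "original" and not (
            self.stand_type == "n/a"
            and self.seeding_density == "n/a"
            and self.harvest_regime == "n/a"
        ):
            raise ValueError("original population must have all treatment fields 'n/a'")


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate {what} ids")


@dataclass
class GenotypeMatrix:
    """Diploid dosage calls with per-allele read depths.

    ``dosage[i, j]`` counts copies of ``snps[j].alt_allele`` in individual
    ``i`` (0, 1, 2, or :data:`MISSING`); ``depth_ref``/``depth_alt`` hold the
    supporting read counts and are retained even where QC blanks the call.
    """

    snps: list[SnpRecord]
    individuals: list[tuple[str, str]]  # (individual_id, population_id)
    dosage: np.ndarray  # (n_individuals, n_snps) int8
    depth_ref: np.ndarray  # (n_individuals, n_snps) int32
    depth_alt: np.ndarray

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        self.depth_ref = np.asarray(self.depth_ref, dtype=np.int32)
        self.depth_alt = np.asarray(self.depth_alt, dtype=np.int32)
        shape = (len(self.individuals), len(self.snps))
        for name in ("dosage", "depth_ref", "depth_alt"):
            arr = getattr(self, name)
            if arr.shape != shape:
                raise ValueError(f"{name} has shape {arr.shape}, expected {shape}")
        if (self.depth_ref < 0).any() or (self.depth_alt < 0).any():
            raise ValueError("read depths must be non-negative")
        valid = np.isin(self.dosage, (MISSING, 0, 1, 2))
        if not valid.all():
            raise ValueError("dosage entries must be 0, 1, 2 or MISSING")
        _check_unique(self.snp_ids, "SNP")
        _check_unique([i for i, _ in self.individuals], "individual")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    @property
    def population_ids(self) -> list[str]:
        """Distinct population labels in order of first appearance."""
        seen: dict[str, None] = {}
        for _, pop in self.individuals:
            seen.setdefault(pop)
        return list(seen)

    def population_mask(self, population_id: str) -> np.ndarray:
        return np.array([pop == population_id for _, pop in self.individuals])

    def subset_snps(self, keep: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        return GenotypeMatrix(
            snps=[self.snps[int(j)] for j in keep],
            individuals=list(self.individuals),
            dosage=self.dosage[:, keep].copy(),
            depth_ref=self.depth_ref[:, keep].copy(),
            depth_alt=self.depth_alt[:, keep].copy(),
        )

    def subset_individuals(self, keep: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        return GenotypeMatrix(
            snps=list(self.snps),
            individuals=[self.individuals[int(i)] for i in keep],
            dosage=self.dosage[keep, :].copy(),
            depth_ref=self.depth_ref[keep, :].copy(),
            depth_alt=self.depth_alt[keep, :].copy(),
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            snps=list(self.snps),
            individuals=list(self.individuals),
            dosage=self.dosage.copy(),
            depth_ref=self.depth_ref.copy(),
            depth_alt=self.depth_alt.copy(),
        )


@dataclass
class PoolCountTable:
    """Reference/alternate read counts for pooled samples.

    Each row is one sequencing library of one pool; ``pools[i]`` is
    ``(pool_id, population_id, replicate_index)`` and ``library_ids[i]``
    records provenance. Several rows may share a ``pool_id`` (replicate
    libraries of the same DNA pool) — they are merged downstream by
    :func:`cloverscan.frequencies.frequencies_from_pools`.
    """

    snps: list[SnpRecord]
    pools: list[tuple[str, str, int]]  # (pool_id, population_id, replicate_index)
    counts_ref: np.ndarray  # (n_pools, n_snps) int64
    counts_alt: np.ndarray
    library_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts_ref = np.asarray(self.counts_ref, dtype=np.int64)
        self.counts_alt = np.asarray(self.counts_alt, dtype=np.int64)
        shape = (len(self.pools), len(self.snps))
        for name in ("counts_ref", "counts_alt"):
            arr = getattr(self, name)
            if arr.shape != shape:
                raise ValueError(f"{name} has shape {arr.shape}, expected {shape}")
        if (self.counts_ref < 0).any() or (self.counts_alt < 0).any():
            raise ValueError("read counts must be non-negative")
        if not self.library_ids:
            self.library_ids = [f"lib{i}" for i in range(len(self.pools))]
        if len(self.library_ids) != len(self.pools):
            raise ValueError("library_ids length must match pools")
        _check_unique(self.snp_ids, "SNP")

    @property
    def n_pools(self) -> int:
        return len(self.pools)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    @property
    def depth(self) -> np.ndarray:
        return self.counts_ref + self.counts_alt

    def subset_snps(self, keep: Sequence[int] | np.ndarray) -> "PoolCountTable":
        keep = np.asarray(keep)
        return PoolCountTable(
            snps=[self.snps[int(j)] for j in keep],
            pools=list(self.pools),
            counts_ref=self.counts_ref[:, keep].copy(),
            counts_alt=self.counts_alt[:, keep].copy(),
            library_ids=list(self.library_ids),
        )


@dataclass
class FrequencyTable:
    """Allele frequency ``q`` of a fixed tracked allele, per population x SNP.

    ``two_n[k, j]`` is the number of successfully genotyped gametes behind
    ``q[k, j]`` (twice the genotyped individuals, or a nominal pool gamete
    count). ``q`` is NaN where no estimate exists. ``tracked_is_alt[j]``
    records whether the tracked allele of SNP ``j`` is the alternate allele —
    the same allele is tracked in every population, so cross-population
    differences are meaningful.
    """

    snps: list[SnpRecord]
    populations: list[str]
    q: np.ndarray  # (n_populations, n_snps) float64, NaN where undefined
    two_n: np.ndarray  # (n_populations, n_snps) int64
    tracked_is_alt: np.ndarray | None = None  # (n_snps,) bool

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=np.float64)
        self.two_n = np.asarray(self.two_n, dtype=np.int64)
        shape = (len(self.populations), len(self.snps))
        if self.q.shape != shape or self.two_n.shape != shape:
            raise ValueError("q/two_n shape mismatch")
        finite = np.isfinite(self.q)
        if ((self.q[finite] < 0) | (self.q[finite] > 1)).any():
            raise ValueError("frequencies must lie in [0, 1]")
        if (self.two_n < 0).any() or (self.two_n % 2 != 0).any():
            raise ValueError("two_n must be even and non-negative")
        if self.tracked_is_alt is None:
            self.tracked_is_alt = np.ones(len(self.snps), dtype=bool)
        else:
            self.tracked_is_alt = np.asarray(self.tracked_is_alt, dtype=bool)
            if self.tracked_is_alt.shape != (len(self.snps),):
                raise ValueError("tracked_is_alt shape mismatch")
        _check_unique(self.snp_ids, "SNP")
        _check_unique(self.populations, "population")

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    def row(self, population_id: str) -> np.ndarray:
        return self.q[self.populations.index(population_id)]

    def two_n_row(self, population_id: str) -> np.ndarray:
        return self.two_n[self.populations.index(population_id)]

    def subset_snps(self, keep: Sequence[int] | np.ndarray) -> "FrequencyTable":
        keep = np.asarray(keep)
        return FrequencyTable(
            snps=[self.snps[int(j)] for j in keep],
            populations=list(self.populations),
            q=self.q[:, keep].copy(),
            two_n=self.two_n[:, keep].copy(),
            tracked_is_alt=self.tracked_is_alt[keep].copy(),
        )

    def to_frame(self):
        """Frequencies as a pandas DataFrame (populations x SNP ids)."""
        import pandas as pd

        return pd.DataFrame(self.q, index=self.populations, columns=self.snp_ids)


__all__ = [
    "MISSING",
    "SnpRecord",
    "PopulationMeta",
    "GenotypeMatrix",
    "PoolCountTable",
    "FrequencyTable",
]
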