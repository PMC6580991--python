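import numpy as np
import pytest

from cloverscan.datatypes import (
    MISSING,
    GenotypeMatrix,
    PoolCountTable,
    PopulationMeta,
    SnpRecord,
)


def make_snps(n, chrom_every=2):
    """n SnpRecords, every ``chrom_every``-th one placed on a chromosome."""
    out = []
    for j in range(n):
        if j % chrom_every == 0:
            out.append(SnpRecord(f"T{j:03d}", f"Tp{j % 7 + 1}", 1000 + 17 * j, "A", "C"))
        else:
            out.append(SnpRecord(f"T{j:03d}", None, None, "G", "T"))
    return out


def random_genotypes(rng, n_ind=12, n_snp=8, pops=("orig", "surv1"), miss_rate=0.15):
    """A random small GenotypeMatrix with plausible depths."""
    snps = make_snps(n_snp)
    individuals = [(f"i{i:03d}", pops[i % len(pops)]) for i in range(n_ind)]
    dosage = rng.integers(0, 3, size=(n_ind, n_snp)).astype(np.int8)
    dosage[rng.random((n_ind, n_snp)) < miss_rate] = MISSING
    depth = rng.integers(0, 40, size=(n_ind, n_snp))
    frac = np.where(dosage == MISSING, 0.5, dosage / 2.0)
    alt = rng.binomial(depth, frac)
    return GenotypeMatrix(snps, individuals, dosage, (depth - alt), alt)


def random_pools(rng, n_pools=3, n_snp=6):
    snps = make_snps(n_snp)
    pools = [(f"pool{i}", f"pop{i % 2}", i) for i in range(n_pools)]
    depth = rng.integers(5, 400, size=(n_pools, n_snp))
    alt = rng.binomial(depth, 0.3)
    return PoolCountTable(snps, pools, depth - alt, alt, [f"lib{i}" for i in range(n_pools)])


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_genotypes(rng):
    return random_genotypes(rng)


@pytest.fixture
def study1_meta():
    return [
        PopulationMeta("orig", "original", n_sampled=88),
        PopulationMeta("S1", "survivor", stand_type="pure", seeding_density="high",
                       harvest_regime="3H", replicate_plot=1, n_sampled=48),
        PopulationMeta("S2", "survivor", stand_type="pure", seeding_density="high",
                       harvest_regime="3H", replicate_plot=2, n_sampled=48),
        PopulationMeta("S3", "survivor", stand_type="pure", seeding_density="high",
                       harvest_regime="5H", replicate_plot=3, n_sampled=47),
        PopulationMeta("S4", "survivor", stand_type="pure", seeding_density="high",
                       harvest_regime="5H", replicate_plot=4, n_sampled=48),
    ]
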