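"""Readers and writers for the package's file dialects.

Genotypes come in two dialects:

* **VCF** with per-sample ``AD`` (per-allele depth) fields, read through
  :mod:`cyvcf2`. Only biallelic records are kept; multiallelic records are
  skipped with a logged count.
* **TSV**: one row per SNP with columns ``snp_id chrom pos ref alt`` followed
  by one ``dosage:refDepth:altDepth`` triplet per individual (missing dosage
  encoded ``.``). A ``##individuals`` pre-header line maps each individual to
  its population. This covers callers that emit tag-based tables rather than
  coordinate VCFs.

Pool counts, frequency tables and scan results are plain TSV. Coordinates are
1-based throughout. Missing numbers serialise as ``NA``.
"""

from __future__ import annotations

import logging
import math
import os
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .datatypes import (
    MISSING,
    FrequencyTable,
    GenotypeMatrix,
    PoolCountTable,
    PopulationMeta,
    SnpRecord,
)

logger = logging.getLogger("cloverscan")

_NA = "NA"


class ParseError(ValueError):
    """Raised when an input file violates its dialect."""


# ---------------------------------------------------------------------------
# genotype TSV dialect
# ---------------------------------------------------------------------------

def write_genotypes_tsv(g: GenotypeMatrix, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        pairs = "\t".join(f"{ind}={pop}" for ind, pop in g.individuals)
        fh.write(f"##individuals\t{pairs}\n")
        header = ["snp_id", "chrom", "pos", "ref", "alt"] + [i for i, _ in g.individuals]
        fh.write("#" + "\t".join(header) + "\n")
        for j, snp in enumerate(g.snps):
            cells = [
                snp.snp_id,
                snp.chromosome or _NA,
                str(snp.position) if snp.position is not None else _NA,
                snp.ref_allele,
                snp.alt_allele,
            ]
            for i in range(g.n_individuals):
                d = g.dosage[i, j]
                ds = "." if d == MISSING else str(int(d))
                cells.append(f"{ds}:{g.depth_ref[i, j]}:{g.depth_alt[i, j]}")
            fh.write("\t".join(cells) + "\n")


def _parse_genotype_tsv(path: str | os.PathLike) -> GenotypeMatrix:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("##individuals"):
            raise ParseError(f"{path}:1: expected '##individuals' header line")
        individuals: list[tuple[str, str]] = []
        for tok in first.rstrip("\n").split("\t")[1:]:
            if "=" not in tok:
                raise ParseError(f"{path}:1: malformed individual entry {tok!r}")
            ind, pop = tok.split("=", 1)
            individuals.append((ind, pop))
        second = fh.readline()
        if not second.startswith("#"):
            raise ParseError(f"{path}:2: expected column header line")
        snps: list[SnpRecord] = []
        dosage_rows, dref_rows, dalt_rows = [], [], []
        for lineno, line in enumerate(fh, start=3):
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split("\t")
            if len(cells) != 5 + len(individuals):
                raise ParseError(
                    f"{path}:{lineno}: expected {5 + len(individuals)} columns, got {len(cells)}"
                )
            chrom = None if cells[1] == _NA else cells[1]
            pos = None if cells[2] == _NA else int(cells[2])
            snps.append(SnpRecord(cells[0], chrom, pos, cells[3], cells[4]))
            drow, rrow, arow = [], [], []
            for tok in cells[5:]:
                try:
                    ds, dr, da = tok.split(":")
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: malformed triplet {tok!r}") from exc
                drow.append(MISSING if ds == "." else int(ds))
                rrow.append(int(dr))
                arow.append(int(da))
            dosage_rows.append(drow)
            dref_rows.append(rrow)
            dalt_rows.append(arow)
    n_ind, n_snp = len(individuals), len(snps)
    dosage = np.full((n_ind, n_snp), MISSING, dtype=np.int8)
    dref = np.zeros((n_ind, n_snp), dtype=np.int32)
    dalt = np.zeros((n_ind, n_snp), dtype=np.int32)
    for j in range(n_snp):
        dosage[:, j] = dosage_rows[j]
        dref[:, j] = dref_rows[j]
        dalt[:, j] = dalt_rows[j]
    return GenotypeMatrix(snps, individuals, dosage, dref, dalt)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def write_genotypes_vcf(g: GenotypeMatrix, path: str | os.PathLike) -> None:
    """Write a minimal VCF 4.2 with GT and AD per sample.

    Population labels are not representable in VCF; pass a sample→population
    mapping to :func:`read_genotypes` when reading back.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n'
        )
        contigs = sorted({s.chromosome for s in g.snps if s.chromosome})
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        if any(s.chromosome is None for s in g.snps):
            fh.write("##contig=<ID=unplaced>\n")
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
        cols += [i for i, _ in g.individuals]
        fh.write("\t".join(cols) + "\n")
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        for j, snp in enumerate(g.snps):
            row = [
                snp.chromosome or "unplaced",
                str(snp.position if snp.position is not None else j + 1),
                snp.snp_id,
                snp.ref_allele,
                snp.alt_allele,
                ".",
                "PASS",
                ".",
                "GT:AD",
            ]
            for i in range(g.n_individuals):
                row.append(
                    f"{gt_map[int(g.dosage[i, j])]}:{g.depth_ref[i, j]},{g.depth_alt[i, j]}"
                )
            fh.write("\t".join(row) + "\n")


def _parse_genotype_vcf(
    path: str | os.PathLike,
    sample_populations: Mapping[str, str] | None = None,
) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    pops = {s: (sample_populations or {}).get(s, "pop0") for s in samples}
    snps: list[SnpRecord] = []
    dosage_cols, dref_cols, dalt_cols = [], [], []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        chrom = None if var.CHROM in ("unplaced", ".", "") else var.CHROM
        snp_id = var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}"
        snps.append(SnpRecord(snp_id, chrom, int(var.POS), var.REF, var.ALT[0]))
        col = np.full(len(samples), MISSING, dtype=np.int8)
        try:
            # gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
            gt = var.gt_types
        except Exception:
            gt = None  # record carries depths but no genotypes
        if gt is not None:
            col[gt == 0] = 0
            col[gt == 1] = 1
            col[gt == 3] = 2
        dosage_cols.append(col)
        ad = var.format("AD")
        if ad is None:
            dref_cols.append(np.zeros(len(samples), dtype=np.int32))
            dalt_cols.append(np.zeros(len(samples), dtype=np.int32))
        else:
            ad = np.asarray(ad, dtype=np.int64)
            ad[ad < 0] = 0  # cyvcf2 encodes missing AD as negative fill
            dref_cols.append(ad[:, 0].astype(np.int32))
            dalt_cols.append(ad[:, 1].astype(np.int32))
    vcf.close()
    if n_multi:
        logger.warning("skipped %d multiallelic record(s) in %s", n_multi, path)
    n_snp = len(snps)
    dosage = np.full((len(samples), n_snp), MISSING, dtype=np.int8)
    dref = np.zeros((len(samples), n_snp), dtype=np.int32)
    dalt = np.zeros((len(samples), n_snp), dtype=np.int32)
    for j in range(n_snp):
        dosage[:, j] = dosage_cols[j]
        dref[:, j] = dref_cols[j]
        dalt[:, j] = dalt_cols[j]
    individuals = [(s, pops[s]) for s in samples]
    return GenotypeMatrix(snps, individuals, dosage, dref, dalt)


def read_genotypes(
    path: str | os.PathLike,
    dialect: str = "tsv",
    sample_populations: Mapping[str, str] | None = None,
) -> GenotypeMatrix:
    """Read a genotype matrix from ``path`` in the given dialect.

    Parameters
    ----------
    dialect : {"tsv", "vcf"}
    sample_populations : mapping, optional
        Sample-id to population-id assignment, used by the VCF dialect (VCF
        itself carries no population labels).
    """
    if dialect == "tsv":
        return _parse_genotype_tsv(path)
    if dialect == "vcf":
        return _parse_genotype_vcf(path, sample_populations)
    raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# pool counts
# ---------------------------------------------------------------------------

_POOL_COLS = ["pool_id", "population_id", "replicate_index", "library_id",
              "snp_id", "chrom", "pos", "ref", "alt", "ref_count", "alt_count"]


def write_pool_counts(p: PoolCountTable, path: str | os.PathLike) -> None:
    rows = []
    for i, (pool_id, pop_id, rep) in enumerate(p.pools):
        for j, snp in enumerate(p.snps):
            rows.append(
                (
                    pool_id,
                    pop_id,
                    rep,
                    p.library_ids[i],
                    snp.snp_id,
                    snp.chromosome or _NA,
                    snp.position if snp.position is not None else _NA,
                    snp.ref_allele,
                    snp.alt_allele,
                    int(p.counts_ref[i, j]),
                    int(p.counts_alt[i, j]),
                )
            )
    pd.DataFrame(rows, columns=_POOL_COLS).to_csv(path, sep="\t", index=False)


def read_pool_counts(path: str | os.PathLike) -> PoolCountTable:
    """Read a pool count table; duplicate (library, snp) rows are summed.

    The minimal column set is ``pool_id snp_id ref_count alt_count``; the
    remaining provenance columns are optional and default sensibly.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype={"pool_id": str, "snp_id": str})
    except pd.errors.EmptyDataError:
        return PoolCountTable([], [], np.zeros((0, 0)), np.zeros((0, 0)), [])
    if df.empty:
        return PoolCountTable([], [], np.zeros((0, 0)), np.zeros((0, 0)), [])
    required = {"pool_id", "snp_id", "ref_count", "alt_count"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    if (df["ref_count"] < 0).any() or (df["alt_count"] < 0).any():
        raise ParseError(f"{path}: negative read counts")
    for col, default in (
        ("population_id", df["pool_id"]),
        ("replicate_index", 0),
        ("library_id", df["pool_id"]),
        ("chrom", _NA),
        ("pos", _NA),
        ("ref", "A"),
        ("alt", "G"),
    ):
        if col not in df.columns:
            df[col] = default
    dup = df.duplicated(subset=["library_id", "snp_id"], keep=False)
    if dup.any():
        logger.info("summed %d duplicate (library, snp) rows in %s", int(dup.sum()), path)
        keys = ["pool_id", "population_id", "replicate_index", "library_id",
                "snp_id", "chrom", "pos", "ref", "alt"]
        df = df.groupby(keys, as_index=False, sort=False, dropna=False).agg(
            {"ref_count": "sum", "alt_count": "sum"}
        )
    snp_order: dict[str, SnpRecord] = {}
    for rec in df[["snp_id", "chrom", "pos", "ref", "alt"]].itertuples(index=False):
        if rec.snp_id not in snp_order:
            chrom = None if pd.isna(rec.chrom) or rec.chrom == _NA else str(rec.chrom)
            pos = None if pd.isna(rec.pos) or rec.pos == _NA else int(rec.pos)
            snp_order[rec.snp_id] = SnpRecord(rec.snp_id, chrom, pos, str(rec.ref), str(rec.alt))
    snps = list(snp_order.values())
    snp_idx = {s.snp_id: j for j, s in enumerate(snps)}
    lib_order: dict[str, tuple[str, str, int]] = {}
    for rec in df[["library_id", "pool_id", "population_id", "replicate_index"]].itertuples(index=False):
        lib_order.setdefault(
            str(rec.library_id), (str(rec.pool_id), str(rec.population_id), int(rec.replicate_index))
        )
    lib_ids = list(lib_order)
    lib_idx = {lid: i for i, lid in enumerate(lib_ids)}
    cref = np.zeros((len(lib_ids), len(snps)), dtype=np.int64)
    calt = np.zeros_like(cref)
    for rec in df.itertuples(index=False):
        i = lib_idx[str(rec.library_id)]
        j = snp_idx[str(rec.snp_id)]
        cref[i, j] = int(rec.ref_count)
        calt[i, j] = int(rec.alt_count)
    pools = [lib_order[lid] for lid in lib_ids]
    return PoolCountTable(snps, pools, cref, calt, lib_ids)


# ---------------------------------------------------------------------------
# frequency tables & scan results
# ---------------------------------------------------------------------------

def write_frequency_table(f: FrequencyTable, path: str | os.PathLike) -> None:
    rows = []
    for j, snp in enumerate(f.snps):
        row: dict[str, object] = {
            "snp_id": snp.snp_id,
            "chrom": snp.chromosome or _NA,
            "pos": snp.position if snp.position is not None else _NA,
            "ref": snp.ref_allele,
            "alt": snp.alt_allele,
            "tracked_is_alt": int(f.tracked_is_alt[j]),
        }
        for k, pop in enumerate(f.populations):
            row[f"q:{pop}"] = f.q[k, j]
            row[f"two_n:{pop}"] = int(f.two_n[k, j])
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, na_rep=_NA, float_format="%.10g")


def read_frequency_table(path: str | os.PathLike) -> FrequencyTable:
    df = pd.read_csv(path, sep="\t", na_values=[_NA], dtype={"snp_id": str})
    pops = [c[2:] for c in df.columns if c.startswith("q:")]
    snps = []
    for rec in df.itertuples(index=False):
        chrom = None if pd.isna(rec.chrom) else str(rec.chrom)
        pos = None if pd.isna(rec.pos) else int(rec.pos)
        snps.append(SnpRecord(str(rec.snp_id), chrom, pos, str(rec.ref), str(rec.alt)))
    q = df[[f"q:{p}" for p in pops]].to_numpy(dtype=float).T
    two_n = df[[f"two_n:{p}" for p in pops]].to_numpy(dtype=np.int64).T
    tracked = df["tracked_is_alt"].to_numpy(dtype=bool)
    return FrequencyTable(snps, pops, q, two_n, tracked)


def write_scan_results(result, path: str | os.PathLike) -> None:
    """Serialise a :class:`cloverscan.scan.ScanResult` as TSV (``NA`` for NaN)."""
    result.to_frame().to_csv(path, sep="\t", index=False, na_rep=_NA, float_format="%.10g")


def read_scan_results(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[_NA], dtype={"snp_id": str})


# ---------------------------------------------------------------------------
# metadata & flat config
# ---------------------------------------------------------------------------

_META_COLS = ["population_id", "role", "stand_type", "seeding_density",
              "harvest_regime", "replicate_plot", "n_sampled"]


def write_population_meta(pops: Iterable[PopulationMeta], path: str | os.PathLike) -> None:
    rows = [[getattr(p, c) for c in _META_COLS] for p in pops]
    pd.DataFrame(rows, columns=_META_COLS).to_csv(path, sep="\t", index=False)


def read_population_meta(path: str | os.PathLike) -> list[PopulationMeta]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for rec in df.itertuples(index=False):
        out.append(
            PopulationMeta(
                population_id=str(rec.population_id),
                role=str(rec.role),
                stand_type=str(rec.stand_type),
                seeding_density=str(rec.seeding_density),
                harvest_regime=str(rec.harvest_regime),
                replicate_plot=int(rec.replicate_plot),
                n_sampled=int(rec.n_sampled),
            )
        )
    return out


def read_config(path: str | os.PathLike) -> dict[str, str]:
    """Read a flat ``key = value`` configuration file (no nesting).

    Blank lines and ``#`` comments are ignored; values are returned as
    strings and coerced by consumers.
    """
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ParseError(f"{path}:{lineno}: expected 'key = value'")
            key, val = line.split("=", 1)
            out[key.strip()] = val.strip()
    return out


def fmt_na(x: float, digits: int = 6) -> str:
    """Format a float, mapping NaN to ``NA`` (shared by report writers)."""
    return _NA if x is None or (isinstance(x, float) and math.isnan(x)) else f"{x:.{digits}g}"


__all__ = [
    "ParseError",
    "read_genotypes",
    "write_genotypes_tsv",
    "write_genotypes_vcf",
    "read_pool_counts",
    "write_pool_counts",
    "read_frequency_table",
    "write_frequency_table",
    "read_scan_results",
    "write_scan_results",
    "read_population_meta",
    "write_population_meta",
    "read_config",
]
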