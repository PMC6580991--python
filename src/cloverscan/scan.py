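"""Replicate-intersection F_ST selection scan with a combined FDR.

The test works on populations sampled from the *same* generation: an original
sown population and survivor populations from replicate field plots (or two
treatment groups of plots). Per SNP and comparison the two-population
fixation index

    F_ST = (q1 - q2)^2 / (4 * q_bar * (1 - q_bar)),   q_bar = (q1 + q2) / 2

is tested with the classic chi-square statistic X^2 = 2N * F_ST on one degree
of freedom, where 2N is the summed genotyped-gamete count of the two samples.
A SNP is declared selected at level P only when **every** required comparison
is individually significant at P (the intersection rule); under the null the
chance of that is ~P^n for n independent comparisons, giving the combined
false-discovery-rate estimate

    FDR(P) = l * P^n / d

with l loci tested, and d loci observed to pass the intersection. Selected
SNPs can be confirmed with a two-sided Fisher exact test on pooled gamete
counts.

The model/results split follows the usual statsmodels pattern:
``SelectionScan(freqs, pops, config).fit()`` returns a :class:`ScanResult`
holding per-SNP statistics, per-level hit counts and FDR estimates, and a
ranked summary table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import FrequencyTable, PopulationMeta

logger = logging.getLogger("cloverscan")

DEFAULT_ALPHA_LEVELS = (0.1, 0.05, 0.01)


# ---------------------------------------------------------------------------
# elementary statistics
# ---------------------------------------------------------------------------

def pairwise_fst(q1, q2):
    """Two-population F_ST, ``(q1-q2)^2 / (4 q_bar (1-q_bar))``.

    Symmetric in its arguments, lies in [0, 1], and equals the
    between-population variance of q divided by ``q_bar(1-q_bar)``. NaN when
    the pair is monomorphic (``q_bar`` of 0 or 1) or either input is NaN.
    Accepts scalars or arrays.
    """
    q1 = np.asarray(q1, dtype=float)
    q2 = np.asarray(q2, dtype=float)
    qbar = (q1 + q2) / 2.0
    denom = 4.0 * qbar * (1.0 - qbar)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, (q1 - q2) ** 2 / np.where(denom > 0, denom, 1.0), np.nan)
    if out.ndim == 0:
        return float(out)
    return out


def chi2_test(fst, two_n_total):
    """Chi-square test of an F_ST value: ``X^2 = 2N * F_ST``, df = 1.

    ``two_n_total`` is the summed genotyped-gamete count of the two
    populations compared. Returns ``(statistic, p)``; NaN propagates.
    """
    fst = np.asarray(fst, dtype=float)
    two_n_total = np.asarray(two_n_total, dtype=float)
    stat = two_n_total * fst
    with np.errstate(invalid="ignore"):
        p = stats.chi2.sf(stat, df=1)
    p = np.where(np.isnan(stat), np.nan, p)
    if stat.ndim == 0:
        return float(stat), float(p)
    return stat, p


@dataclass(frozen=True)
class FdrEstimate:
    """Combined FDR ``l * P^n / d`` for one significance level.

    ``l`` loci tested, per-test level ``P``, ``n`` independent comparisons,
    ``d`` loci significant in all of them. NaN when ``d`` = 0.
    """

    P: float
    l: int
    n: int
    d: int
    fdr: float

    def as_dict(self) -> dict:
        return {"P": self.P, "l": self.l, "n": self.n, "d": self.d, "fdr": self.fdr}


def combined_fdr(l: int, P: float, n: int, d: int) -> FdrEstimate:
    """False-discovery-rate estimate for the replicate-intersection rule.

    ``l * P^n`` null loci are expected to be significant in all ``n``
    independent comparisons by chance; ``d`` were observed.
    """
    if l < 1 or n < 1 or not 0 < P < 1 or d < 0:
        raise ValueError("require l >= 1, n >= 1, 0 < P < 1, d >= 0")
    fdr = l * P**n / d if d > 0 else float("nan")
    return FdrEstimate(P=P, l=l, n=n, d=d, fdr=fdr)


def fisher_confirm(
    counts1: tuple[int, int], counts2: tuple[int, int]
) -> float:
    """Two-sided Fisher exact p for a 2x2 table of (alt, ref) gamete counts.

    The two-sided p sums the probabilities of all tables (at fixed margins)
    no more likely than the observed one. Empty margins give p = 1.
    """
    a1, r1 = counts1
    a2, r2 = counts2
    if min(a1, r1, a2, r2) < 0:
        raise ValueError("counts must be non-negative")
    table = np.array([[a1, r1], [a2, r2]])
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        return 1.0
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


# ---------------------------------------------------------------------------
# the scan model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScanConfig:
    """Configuration of an intersection scan.

    ``comparison_mode``:
      * ``vs_original`` — each survivor population against the original one.
      * ``vs_opposite_group_mean`` — each population against the unweighted
        mean frequency of the opposite treatment group (grouped by stand
        type); the group mean carries the *sum* of its pools' gamete counts.

    ``n_replicates_independent`` is the exponent n of the combined FDR; with
    two opposing groups of plots only half the comparisons are independent,
    so it defaults to the number of comparisons in ``vs_original`` mode and
    to the group size in ``vs_opposite_group_mean`` mode. ``require_all``
    (default: every comparison) is how many comparisons must be significant.
    """

    alpha_levels: tuple[float, ...] = DEFAULT_ALPHA_LEVELS
    comparison_mode: str = "vs_original"
    n_replicates_independent: int | None = None
    require_all: int | None = None
    group_field: str = "stand_type"
    run_fisher: bool = True

    def __post_init__(self) -> None:
        if not all(0 < a < 1 for a in self.alpha_levels):
            raise ValueError("alpha levels must lie in (0, 1)")
        if self.comparison_mode not in ("vs_original", "vs_opposite_group_mean"):
            raise ValueError(f"unknown comparison_mode {self.comparison_mode!r}")


class SelectionScan:
    """Model object: an intersection scan of a frequency table.

    Parameters
    ----------
    freqs : FrequencyTable
        Populations x SNPs frequencies with gamete counts, already filtered.
    populations : sequence of PopulationMeta
        Metadata for every row of ``freqs`` (role / treatment labels).
    config : ScanConfig
    """

    def __init__(
        self,
        freqs: FrequencyTable,
        populations: Sequence[PopulationMeta],
        config: ScanConfig = ScanConfig(),
    ) -> None:
        self.freqs = freqs
        self.populations = list(populations)
        self.config = config
        by_id = {p.population_id: p for p in self.populations}
        missing = [pid for pid in freqs.populations if pid not in by_id]
        if missing:
            raise ValueError(f"no metadata for populations {missing}")
        self._meta = [by_id[pid] for pid in freqs.populations]

    # -- comparison construction -------------------------------------------
    def _comparisons(self):
        """Yield (label, q_a, two_n_a, q_b, two_n_b, shift_sign_base) arrays.

        Convention: the *first* member of each pair is the reference
        (original population or opposite-group mean); shifts are measured as
        q_focal - q_reference.
        """
        f = self.freqs
        mode = self.config.comparison_mode
        comps = []
        import warnings
        if mode == "vs_original":
            orig = [k for k, m in enumerate(self._meta) if m.role == "original"]
            if len(orig) != 1:
                raise ValueError("vs_original mode needs exactly one original population")
            survivors = [k for k, m in enumerate(self._meta) if m.role == "survivor"]
            if len(survivors) < 2:
                raise ValueError("intersection scan needs at least two survivor populations")
            o = orig[0]
            for k in survivors:
                comps.append(
                    (f.populations[k], f.q[o], f.two_n[o], f.q[k], f.two_n[k])
                )
            default_n = len(survivors)
        else:
            groups: dict[str, list[int]] = {}
            for k, m in enumerate(self._meta):
                groups.setdefault(getattr(m, self.config.group_field), []).append(k)
            if len(groups) != 2:
                raise ValueError(
                    f"vs_opposite_group_mean needs exactly two {self.config.group_field} groups, "
                    f"got {sorted(groups)}"
                )
            (ga, rows_a), (gb, rows_b) = groups.items()
            means = {}
            for gname, rows in ((ga, rows_a), (gb, rows_b)):
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    mean_q = np.nanmean(f.q[rows], axis=0)
                mean_q = np.where(np.isnan(f.q[rows]).any(axis=0), np.nan, mean_q)
                means[gname] = (mean_q, f.two_n[rows].sum(axis=0))
            for gname, opp in ((ga, gb), (gb, ga)):
                mq, mn = means[opp]
                for k in groups[gname]:
                    comps.append((f.populations[k], mq, mn, f.q[k], f.two_n[k]))
            default_n = min(len(rows_a), len(rows_b))
        return comps, default_n

    def fit(self) -> "ScanResult":
        cfg = self.config
        comps, default_n = self._comparisons()
        labels = [c[0] for c in comps]
        n_comp = len(comps)
        n_snps = self.freqs.n_snps
        fst = np.full((n_comp, n_snps), np.nan)
        chi2 = np.full((n_comp, n_snps), np.nan)
        pval = np.full((n_comp, n_snps), np.nan)
        shift = np.full((n_comp, n_snps), np.nan)
        for c, (_, q_ref, n_ref, q_foc, n_foc) in enumerate(comps):
            fst[c] = pairwise_fst(q_ref, q_foc)
            chi2[c], pval[c] = chi2_test(fst[c], n_ref + n_foc)
            shift[c] = q_foc - q_ref
        tested = np.isfinite(pval).all(axis=0)
        require = cfg.require_all if cfg.require_all is not None else n_comp
        levels = tuple(sorted(cfg.alpha_levels, reverse=True))
        selected = {
            P: tested & ((pval < P).sum(axis=0) >= require) for P in levels
        }
        l = int(tested.sum())
        n_indep = cfg.n_replicates_independent or default_n
        fdr = {}
        for P in levels:
            d = int(selected[P].sum())
            fdr[P] = combined_fdr(l, P, n_indep, d) if l > 0 else None
            if fdr[P] is not None:
                logger.info(
                    "level P<%g: l=%d, d=%d, FDR=%s", P, l, d,
                    f"{fdr[P].fdr:.3g}" if np.isfinite(fdr[P].fdr) else "NA",
                )
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN SNPs
            mean_fst = np.nanmean(fst, axis=0)
            mean_abs_shift = np.nanmean(np.abs(shift), axis=0)
        sgn = np.sign(shift)
        consistent = tested & (np.abs(sgn.sum(axis=0)) == n_comp)
        fisher_p = np.full(n_snps, np.nan)
        if cfg.run_fisher and cfg.comparison_mode == "vs_original":
            fisher_p = self._fisher_pass(selected[levels[0]])
        return ScanResult(
            snps=list(self.freqs.snps),
            comparison_labels=labels,
            fst_per_comparison=fst,
            chi2_per_comparison=chi2,
            p_per_comparison=pval,
            shift_per_comparison=shift,
            tested=tested,
            selected_at=selected,
            mean_fst=mean_fst,
            mean_abs_shift=mean_abs_shift,
            shift_direction_consistent=consistent,
            fisher_p=fisher_p,
            l=l,
            n_independent=n_indep,
            fdr_by_level={P: fdr[P] for P in levels if fdr[P] is not None},
            freqs=self.freqs,
            meta=self._meta,
            config=cfg,
        )

    def _fisher_pass(self, candidates: np.ndarray) -> np.ndarray:
        """Fisher exact test: combined survivors vs original, per candidate SNP."""
        f = self.freqs
        orig = [k for k, m in enumerate(self._meta) if m.role == "original"][0]
        surv = [k for k, m in enumerate(self._meta) if m.role == "survivor"]
        out = np.full(f.n_snps, np.nan)
        for j in np.flatnonzero(candidates):
            ao = int(round(f.q[orig, j] * f.two_n[orig, j]))
            ro = int(f.two_n[orig, j]) - ao
            a_s = sum(int(round(f.q[k, j] * f.two_n[k, j])) for k in surv)
            r_s = sum(int(f.two_n[k, j]) for k in surv) - a_s
            out[j] = fisher_confirm((a_s, r_s), (ao, ro))
        return out


@dataclass
class ScanResult:
    """Fitted intersection scan: per-SNP statistics and per-level FDRs."""

    snps: list
    comparison_labels: list[str]
    fst_per_comparison: np.ndarray  # (n_comparisons, n_snps)
    chi2_per_comparison: np.ndarray
    p_per_comparison: np.ndarray
    shift_per_comparison: np.ndarray
    tested: np.ndarray  # (n_snps,) bool
    selected_at: dict[float, np.ndarray]
    mean_fst: np.ndarray
    mean_abs_shift: np.ndarray
    shift_direction_consistent: np.ndarray
    fisher_p: np.ndarray
    l: int
    n_independent: int
    fdr_by_level: dict[float, FdrEstimate]
    freqs: FrequencyTable = None
    meta: list[PopulationMeta] = field(default_factory=list)
    config: ScanConfig = None

    @property
    def levels(self) -> tuple[float, ...]:
        return tuple(self.selected_at)

    def d(self, P: float) -> int:
        return int(self.selected_at[P].sum())

    def fdr_table(self) -> pd.DataFrame:
        return pd.DataFrame([e.as_dict() for e in self.fdr_by_level.values()])

    def to_frame(self) -> pd.DataFrame:
        """Per-SNP long-format results table (deterministic column order)."""
        cols: dict[str, object] = {
            "snp_id": [s.snp_id for s in self.snps],
            "chrom": [s.chromosome or "NA" for s in self.snps],
            "pos": [s.position if s.position is not None else "NA" for s in self.snps],
            "tested": self.tested.astype(int),
        }
        for c, lab in enumerate(self.comparison_labels):
            cols[f"fst:{lab}"] = self.fst_per_comparison[c]
            cols[f"p:{lab}"] = self.p_per_comparison[c]
        cols["mean_fst"] = self.mean_fst
        cols["mean_abs_shift"] = self.mean_abs_shift
        for P in self.levels:
            cols[f"selected_at:{P:g}"] = self.selected_at[P].astype(int)
        cols["direction_consistent"] = self.shift_direction_consistent.astype(int)
        cols["fisher_p"] = self.fisher_p
        return pd.DataFrame(cols)

    def summary(self, level: float | None = None) -> pd.DataFrame:
        """Ranked report of selected SNPs (largest mean |shift| first).

        Columns: SNP id, map position, reference-population q (2N), mean
        focal q ± s.e. with the 2N range, mean absolute shift, mean F_ST
        ± s.e., Fisher p.
        """
        level = level if level is not None else max(self.levels)
        sel = np.flatnonzero(self.selected_at[level])
        rows = []
        n_comp = len(self.comparison_labels)
        ref_q = ref_2n = None
        if self.config is not None and self.config.comparison_mode == "vs_original" and self.freqs is not None:
            orig = [k for k, m in enumerate(self.meta) if m.role == "original"][0]
            ref_q, ref_2n = self.freqs.q[orig], self.freqs.two_n[orig]
            foc_rows = [k for k, m in enumerate(self.meta) if m.role == "survivor"]
        for j in sel:
            snp = self.snps[j]
            focal = self.shift_per_comparison[:, j] + (
                ref_q[j] if ref_q is not None else 0.0
            )
            mean_focal = float(np.nanmean(focal))
            se_focal = float(np.nanstd(focal, ddof=1) / np.sqrt(n_comp))
            fst_j = self.fst_per_comparison[:, j]
            rows.append(
                {
                    "snp_id": snp.snp_id,
                    "map_position": (
                        f"{snp.chromosome}_{snp.position}" if snp.is_chromosomal else "NA"
                    ),
                    "ref_q": float(ref_q[j]) if ref_q is not None else np.nan,
                    "ref_two_n": int(ref_2n[j]) if ref_2n is not None else 0,
                    "mean_focal_q": mean_focal,
                    "se_focal_q": se_focal,
                    "focal_two_n_min": (
                        int(min(self.freqs.two_n[k, j] for k in foc_rows))
                        if ref_q is not None else 0
                    ),
                    "focal_two_n_max": (
                        int(max(self.freqs.two_n[k, j] for k in foc_rows))
                        if ref_q is not None else 0
                    ),
                    "mean_abs_shift": float(self.mean_abs_shift[j]),
                    "mean_fst": float(np.nanmean(fst_j)),
                    "se_fst": float(np.nanstd(fst_j, ddof=1) / np.sqrt(n_comp)),
                    "fisher_p": float(self.fisher_p[j]),
                }
            )
        df = pd.DataFrame(
            rows,
            columns=[
                "snp_id", "map_position", "ref_q", "ref_two_n", "mean_focal_q",
                "se_focal_q", "focal_two_n_min", "focal_two_n_max",
                "mean_abs_shift", "mean_fst", "se_fst", "fisher_p",
            ],
        )
        if not df.empty:
            df = df.sort_values("mean_abs_shift", ascending=False, kind="mergesort")
            df = df.reset_index(drop=True)
        return df


def summarize_scan(result: ScanResult, config: ScanConfig | None = None):
    """Per-level (d, FdrEstimate) pairs plus the ranked report table."""
    per_level = {P: (result.d(P), result.fdr_by_level.get(P)) for P in result.levels}
    return per_level, result.summary()


__all__ = [
    "DEFAULT_ALPHA_LEVELS",
    "pairwise_fst",
    "chi2_test",
    "combined_fdr",
    "fisher_confirm",
    "FdrEstimate",
    "ScanConfig",
    "SelectionScan",
    "ScanResult",
    "summarize_scan",
]
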