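"""Balanced two-way fixed-effects ANOVA on per-SNP allele frequencies.

Candidate SNPs (e.g. an external outlier scan's hit list) are tested for
effects of stand type, seeding density and their interaction on the per-plot
allele frequency. The design is the balanced 2x2 layout with r replicate
plots per cell, so the classical decomposition from cell means applies and
type-I and type-III sums of squares coincide:

    SS_A = 2r * sum_a (mean_a - grand)^2          (stand type)
    SS_B = 2r * sum_b (mean_b - grand)^2          (seeding density)
    SS_AB = r * sum_ab (cell_ab - mean_a - mean_b + grand)^2
    SS_error = SS_total - SS_A - SS_B - SS_AB

Each effect has 1 numerator degree of freedom; the error has N - 4. No
multiple-testing correction is applied across SNPs at this stage — candidate
lists are short and reported per-SNP.

``TreatmentAnova(freqs, design).fit()`` is the model/results pair;
:func:`two_way_anova` is the single-SNP primitive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import FrequencyTable

STAR_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def _stars(p: float) -> str:
    for level, mark in STAR_LEVELS:
        if p < level:
            return mark
    return ""


@dataclass(frozen=True)
class AnovaRow:
    """Per-SNP two-way ANOVA decomposition with (1, error-df) F tests."""

    snp_id: str
    ss_stand: float
    ss_density: float
    ss_interaction: float
    ss_error: float
    df_error: int
    f_stand: float
    f_density: float
    f_interaction: float
    p_stand: float
    p_density: float
    p_interaction: float
    diff_stand: float  # |mean q difference| between stand types
    diff_density: float

    @property
    def stars(self) -> tuple[str, str, str]:
        return (_stars(self.p_stand), _stars(self.p_density), _stars(self.p_interaction))

    def as_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "snp_id", "diff_stand", "diff_density",
            "ss_stand", "ss_density", "ss_interaction", "ss_error", "df_error",
            "f_stand", "f_density", "f_interaction",
            "p_stand", "p_density", "p_interaction",
        )}
        d["stars_stand"], d["stars_density"], d["stars_interaction"] = self.stars
        return d


def two_way_anova(
    values: Sequence[float],
    stand: Sequence[str],
    density: Sequence[str],
    snp_id: str = "",
) -> AnovaRow:
    """Classical balanced 2x2 decomposition for one SNP.

    ``values`` are per-plot allele frequencies (replicate pools already
    averaged per plot); ``stand`` and ``density`` give each plot's factor
    levels. The design must be balanced with >= 2 replicates per cell.
    A completely constant response gives all-zero sums of squares and
    p = 1 by convention.
    """
    y = np.asarray(values, dtype=float)
    stand = np.asarray(stand)
    density = np.asarray(density)
    a_levels = sorted(set(stand.tolist()))
    b_levels = sorted(set(density.tolist()))
    if len(a_levels) != 2 or len(b_levels) != 2:
        raise ValueError("two_way_anova requires exactly two levels per factor")
    cells = {}
    for a in a_levels:
        for b in b_levels:
            sel = (stand == a) & (density == b)
            cells[(a, b)] = y[sel]
    sizes = {k: len(v) for k, v in cells.items()}
    r = next(iter(sizes.values()))
    if len(set(sizes.values())) != 1 or r < 2:
        raise ValueError(
            "unbalanced design: this routine supports only balanced 2x2 layouts "
            f"with >= 2 replicate plots per cell (cell sizes {sizes})"
        )
    n = len(y)
    grand = y.mean()
    mean_a = {a: y[stand == a].mean() for a in a_levels}
    mean_b = {b: y[density == b].mean() for b in b_levels}
    ss_a = 2 * r * sum((mean_a[a] - grand) ** 2 for a in a_levels)
    ss_b = 2 * r * sum((mean_b[b] - grand) ** 2 for b in b_levels)
    ss_ab = r * sum(
        (cells[(a, b)].mean() - mean_a[a] - mean_b[b] + grand) ** 2
        for a in a_levels
        for b in b_levels
    )
    ss_total = float(((y - grand) ** 2).sum())
    ss_err = ss_total - ss_a - ss_b - ss_ab
    ss_err = max(ss_err, 0.0)
    df_err = n - 4
    ms_err = ss_err / df_err

    def ftest(ss: float) -> tuple[float, float]:
        if ms_err == 0.0:
            return (0.0, 1.0) if ss == 0.0 else (np.inf, 0.0)
        f = ss / ms_err
        return f, float(stats.f.sf(f, 1, df_err))

    f_a, p_a = ftest(ss_a)
    f_b, p_b = ftest(ss_b)
    f_ab, p_ab = ftest(ss_ab)
    return AnovaRow(
        snp_id=snp_id,
        ss_stand=float(ss_a),
        ss_density=float(ss_b),
        ss_interaction=float(ss_ab),
        ss_error=float(ss_err),
        df_error=df_err,
        f_stand=float(f_a),
        f_density=float(f_b),
        f_interaction=float(f_ab),
        p_stand=p_a,
        p_density=p_b,
        p_interaction=p_ab,
        diff_stand=abs(mean_a[a_levels[0]] - mean_a[a_levels[1]]),
        diff_density=abs(mean_b[b_levels[0]] - mean_b[b_levels[1]]),
    )


def classify_candidates(
    rows: Sequence[AnovaRow], alpha: float = 0.05
) -> dict[str, list[str]]:
    """Partition candidate SNPs by which main effects are significant.

    Returns ``{"stand_only": [...], "density_only": [...], "both": [...],
    "neither": [...]}`` at the given per-test level.
    """
    out: dict[str, list[str]] = {
        "stand_only": [], "density_only": [], "both": [], "neither": []
    }
    for row in rows:
        s = row.p_stand < alpha
        d = row.p_density < alpha
        key = "both" if (s and d) else "stand_only" if s else "density_only" if d else "neither"
        out[key].append(row.snp_id)
    return out


class TreatmentAnova:
    """Model object: two-way treatment ANOVA over a candidate SNP list.

    Parameters
    ----------
    freqs : FrequencyTable
        Per-plot frequencies (replicate pools averaged beforehand).
    design : mapping population_id -> (stand_type, seeding_density)
    snp_ids : sequence of str, optional
        Candidate subset; defaults to every SNP in ``freqs``.
    """

    def __init__(
        self,
        freqs: FrequencyTable,
        design: Mapping[str, tuple[str, str]],
        snp_ids: Sequence[str] | None = None,
    ) -> None:
        missing = [p for p in freqs.populations if p not in design]
        if missing:
            raise ValueError(f"populations without design labels: {missing}")
        self.freqs = freqs
        self.design = dict(design)
        self.snp_ids = list(snp_ids) if snp_ids is not None else freqs.snp_ids

    def fit(self) -> "AnovaResult":
        stand = [self.design[p][0] for p in self.freqs.populations]
        density = [self.design[p][1] for p in self.freqs.populations]
        idx = {s: j for j, s in enumerate(self.freqs.snp_ids)}
        unknown = [s for s in self.snp_ids if s not in idx]
        if unknown:
            raise ValueError(f"candidate SNPs absent from the frequency table: {unknown[:5]}")
        rows = []
        for sid in self.snp_ids:
            y = self.freqs.q[:, idx[sid]]
            if not np.isfinite(y).all():
                continue  # untestable: missing plot frequency
            rows.append(two_way_anova(y, stand, density, snp_id=sid))
        return AnovaResult(rows=rows)


@dataclass
class AnovaResult:
    rows: list[AnovaRow]

    def classify(self, alpha: float = 0.05) -> dict[str, list[str]]:
        return classify_candidates(self.rows, alpha)

    def class_counts(self, alpha: float = 0.05) -> dict[str, int]:
        return {k: len(v) for k, v in self.classify(alpha).items()}

    def summary(self) -> pd.DataFrame:
        """Report table: per-SNP factor-level frequency differences and
        significance stars for each effect."""
        return pd.DataFrame([r.as_dict() for r in self.rows])

    def to_tsv(self, path) -> None:
        self.summary().to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")


__all__ = [
    "AnovaRow",
    "two_way_anova",
    "classify_candidates",
    "TreatmentAnova",
    "AnovaResult",
]
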