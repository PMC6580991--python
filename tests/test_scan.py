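"""The intersection F_ST scan and its elementary statistics."""

import numpy as np
import pytest
from scipy import stats

from cloverscan.datatypes import FrequencyTable, PopulationMeta
from cloverscan.scan import (
    ScanConfig,
    SelectionScan,
    chi2_test,
    combined_fdr,
    fisher_confirm,
    pairwise_fst,
)

from conftest import make_snps


class TestPairwiseFst:
    def test_identical_populations(self):
        assert pairwise_fst(0.3, 0.3) == pytest.approx(0.0)

    def test_fixed_difference(self):
        assert pairwise_fst(0.0, 1.0) == pytest.approx(1.0)

    def test_hand_value(self):
        # (0.2 - 0.4)^2 / (4 * 0.3 * 0.7)
        assert pairwise_fst(0.2, 0.4) == pytest.approx(0.047619, abs=1e-6)

    def test_symmetric_and_bounded(self):
        rng = np.random.default_rng(0)
        q1, q2 = rng.uniform(0, 1, (2, 1000))
        f12 = pairwise_fst(q1, q2)
        f21 = pairwise_fst(q2, q1)
        np.testing.assert_allclose(f12, f21)
        ok = np.isfinite(f12)
        assert ((f12[ok] >= 0) & (f12[ok] <= 1)).all()

    def test_monomorphic_pair_is_na(self):
        assert np.isnan(pairwise_fst(0.0, 0.0))
        assert np.isnan(pairwise_fst(1.0, 1.0))

    def test_equals_variance_form(self):
        """The ratio form equals between-population variance over
        q_bar(1-q_bar) — algebraically identical for two populations."""
        rng = np.random.default_rng(99)
        q1, q2 = rng.uniform(0.001, 0.999, (2, 100_000))
        qbar = (q1 + q2) / 2
        var_form = ((q1**2 + q2**2) / 2 - qbar**2) / (qbar * (1 - qbar))
        np.testing.assert_allclose(pairwise_fst(q1, q2), var_form, atol=1e-12)


class TestChi2:
    def test_zero_fst(self):
        stat, p = chi2_test(0.0, 200)
        assert stat == 0.0 and p == pytest.approx(1.0)

    def test_hand_value(self):
        stat, p = chi2_test(0.047619, 200)
        assert stat == pytest.approx(9.5238, abs=1e-4)
        assert p == pytest.approx(0.00203, abs=5e-5)

    def test_p_decreasing_in_gamete_count(self):
        ps = [chi2_test(0.02, n)[1] for n in (50, 100, 200, 400, 800)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_na_propagates(self):
        _, p = chi2_test(float("nan"), 100)
        assert np.isnan(p)


class TestCombinedFdr:
    def test_na_when_no_discoveries(self):
        assert np.isnan(combined_fdr(1000, 0.05, 4, 0).fdr)

    def test_decreasing_in_d(self):
        vals = [combined_fdr(4966, 0.1, 4, d).fdr for d in (1, 5, 20, 50)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            combined_fdr(0, 0.1, 4, 1)
        with pytest.raises(ValueError):
            combined_fdr(100, 1.5, 4, 1)


def fisher_enumeration_oracle(a1, r1, a2, r2):
    """Two-sided exact p by full hypergeometric enumeration: sum the
    probabilities of every table (at fixed margins) no more likely than the
    observed one."""
    M = a1 + r1 + a2 + r2
    K = a1 + a2  # total alt gametes
    N = a1 + r1  # row-1 margin
    rv = stats.hypergeom(M, K, N)
    ks = np.arange(max(0, N + K - M), min(K, N) + 1)
    pmf = rv.pmf(ks)
    obs = rv.pmf(a1)
    return float(pmf[pmf <= obs * (1 + 1e-9)].sum())


class TestFisher:
    def test_identical_proportions(self):
        assert fisher_confirm((10, 10), (10, 10)) == pytest.approx(1.0)

    def test_extreme_table_matches_enumeration(self):
        p = fisher_confirm((20, 0), (10, 10))
        assert p == pytest.approx(fisher_enumeration_oracle(20, 0, 10, 10), abs=1e-12)
        assert p == pytest.approx(0.000436, abs=1e-6)

    def test_equals_enumeration_oracle_on_grid(self):
        for a1 in range(0, 12, 3):
            for r1 in range(1, 12, 4):
                for a2 in range(0, 12, 3):
                    for r2 in range(1, 12, 4):
                        got = fisher_confirm((a1, r1), (a2, r2))
                        want = fisher_enumeration_oracle(a1, r1, a2, r2)
                        assert got == pytest.approx(want, abs=1e-10), (a1, r1, a2, r2)

    def test_two_sided_at_least_one_sided(self):
        a1, r1, a2, r2 = 15, 5, 8, 12
        two = fisher_confirm((a1, r1), (a2, r2))
        one = stats.fisher_exact([[a1, r1], [a2, r2]], alternative="greater")[1]
        assert two >= one - 1e-12

    def test_empty_margin(self):
        assert fisher_confirm((0, 10), (0, 5)) == 1.0


def study1_freqs(q_rows, two_n_rows, n_snps=None):
    q = np.array(q_rows, dtype=float)
    two_n = np.array(two_n_rows, dtype=np.int64)
    pops = ["orig"] + [f"S{i}" for i in range(1, q.shape[0])]
    return FrequencyTable(make_snps(q.shape[1]), pops, q, two_n)


def study1_pops(n_survivors=4):
    pops = [PopulationMeta("orig", "original", n_sampled=88)]
    for i in range(1, n_survivors + 1):
        pops.append(PopulationMeta(f"S{i}", "survivor", n_sampled=48))
    return pops


class TestIntersectionScan:
    def test_three_of_four_significant_is_not_selected(self):
        # survivor S4 matches the original exactly -> its p ~ 1
        f = study1_freqs(
            [[0.10], [0.35], [0.35], [0.35], [0.10]],
            [[160], [100], [100], [100], [100]],
        )
        res = SelectionScan(f, study1_pops(), ScanConfig(alpha_levels=(0.05,))).fit()
        assert res.d(0.05) == 0
        assert (res.p_per_comparison[:3, 0] < 0.05).all()

    def test_constructed_counts_selected(self):
        # q_orig = 0.10 (2N=160) vs four survivors at 0.30 (2N=100 each):
        # each pair has X^2 = 260 * 0.0625 = 16.25, p ~ 5.5e-5 < 0.05
        f = study1_freqs(
            [[0.10], [0.30], [0.30], [0.30], [0.30]],
            [[160], [100], [100], [100], [100]],
        )
        res = SelectionScan(f, study1_pops(), ScanConfig(alpha_levels=(0.05,))).fit()
        assert res.d(0.05) == 1
        np.testing.assert_allclose(res.fst_per_comparison[:, 0], 0.0625, atol=1e-9)
        assert res.fdr_by_level[0.05].n == 4

    def test_selected_at_monotone_across_levels(self):
        rng = np.random.default_rng(5)
        q = np.vstack([rng.uniform(0.1, 0.9, 300)] * 5) + rng.normal(0, 0.05, (5, 300))
        q = np.clip(q, 0.01, 0.99)
        f = study1_freqs(q, np.full((5, 300), 120))
        res = SelectionScan(f, study1_pops(), ScanConfig()).fit()
        assert not (res.selected_at[0.05] & ~res.selected_at[0.1]).any()
        assert not (res.selected_at[0.01] & ~res.selected_at[0.05]).any()

    def test_missing_frequency_excluded_from_l(self):
        f = study1_freqs(
            [[0.10, np.nan], [0.30, 0.3], [0.30, 0.3], [0.30, 0.3], [0.30, 0.3]],
            [[160, 0], [100, 100], [100, 100], [100, 100], [100, 100]],
        )
        res = SelectionScan(f, study1_pops(), ScanConfig(alpha_levels=(0.05,))).fit()
        assert res.l == 1
        assert not res.tested[1]

    def test_group_mean_mode_builds_eight_comparisons_with_n_four(self):
        rng = np.random.default_rng(2)
        pops = []
        ids = []
        for stand in ("pure", "mixed"):
            for i in range(4):
                pid = f"{stand[:2]}{i}"
                ids.append(pid)
                pops.append(
                    PopulationMeta(pid, "survivor", stand_type=stand,
                                   seeding_density="high", harvest_regime="3H",
                                   replicate_plot=i, n_sampled=100)
                )
        q = np.clip(rng.uniform(0.2, 0.8, (8, 50)), 0, 1)
        f = FrequencyTable(make_snps(50), ids, q, np.full((8, 50), 200))
        res = SelectionScan(
            f, pops, ScanConfig(comparison_mode="vs_opposite_group_mean")
        ).fit()
        assert len(res.comparison_labels) == 8
        assert res.n_independent == 4
        assert res.fdr_by_level[0.1].n == 4


class TestSummary:
    def test_table_row_shift_and_ordering(self):
        # one strongly shifted SNP, one mildly shifted
        f = study1_freqs(
            [[0.46, 0.30], [0.68, 0.36], [0.67, 0.35], [0.69, 0.37], [0.68, 0.36]],
            np.full((5, 2), 100),
        )
        res = SelectionScan(f, study1_pops(), ScanConfig(alpha_levels=(0.1,))).fit()
        df = res.summary(0.1)
        assert list(df.mean_abs_shift) == sorted(df.mean_abs_shift, reverse=True)
        top = df.iloc[0]
        assert top.mean_abs_shift == pytest.approx(0.22, abs=1e-9)
        assert top.mean_focal_q == pytest.approx(0.68, abs=1e-9)

    def test_se_is_sd_over_two_for_four_comparisons(self):
        f = study1_freqs(
            [[0.10], [0.30], [0.32], [0.28], [0.31]],
            [[160], [100], [100], [100], [100]],
        )
        res = SelectionScan(f, study1_pops(), ScanConfig(alpha_levels=(0.1,))).fit()
        df = res.summary(0.1)
        fsts = res.fst_per_comparison[:, 0]
        assert df.iloc[0].se_fst == pytest.approx(np.std(fsts, ddof=1) / 2, rel=1e-9)

    def test_empty_selection_gives_empty_report_and_na_fdr(self):
        f = study1_freqs(
            [[0.30], [0.30], [0.30], [0.30], [0.30]],
            [[160], [100], [100], [100], [100]],
        )
        res = SelectionScan(f, study1_pops(), ScanConfig(alpha_levels=(0.05,))).fit()
        assert res.summary(0.05).empty
        assert np.isnan(res.fdr_by_level[0.05].fdr)

    def test_fisher_confirmation_on_selected_snps(self):
        f = study1_freqs(
            [[0.10], [0.30], [0.30], [0.30], [0.30]],
            [[160], [100], [100], [100], [100]],
        )
        res = SelectionScan(f, study1_pops(), ScanConfig(alpha_levels=(0.05,))).fit()
        # combined survivors: 4 * 30 alt of 4 * 100; original: 16 of 160
        want = fisher_confirm((120, 280), (16, 144))
        assert res.fisher_p[0] == pytest.approx(want, abs=1e-12)
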