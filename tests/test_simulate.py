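"""The viability-selection simulator: determinism, Hardy-Weinberg,
selection expectations, read models and pooling noise."""

import numpy as np
import pytest
from scipy import stats

from cloverscan.datatypes import MISSING
from cloverscan.filters import FilterConfig, filter_genotype_calls
from cloverscan.scan import pairwise_fst
from cloverscan.simulate import (
    SimConfig,
    apply_viability_selection,
    draw_truth,
    expected_post_selection_freq,
    sample_cohort,
    simulate_base_population,
    simulate_gbs_reads,
    simulate_pool_reads,
    simulate_study1,
    simulate_study3,
)


def neutral_cfg(**kw):
    base = dict(n_selected=0, n_stand_loci=0, n_density_loci=0)
    base.update(kw)
    return SimConfig(**base)


class TestBasePopulation:
    def test_deterministic_from_seed(self):
        cfg = SimConfig(seed=77, n_loci=60, n_sown=100, n_survivors=30)
        a, ta = simulate_base_population(cfg)
        b, tb = simulate_base_population(cfg)
        np.testing.assert_array_equal(a.dosage, b.dosage)
        np.testing.assert_array_equal(ta.base_freq, tb.base_freq)
        assert ta.selected_indices.tolist() == tb.selected_indices.tolist()

    def test_zero_divergence_gives_identical_subpopulations(self):
        cfg = neutral_cfg(seed=3, n_loci=500, divergence_fst=0.0)
        truth = draw_truth(cfg)
        fst = pairwise_fst(truth.subpop_freq[0], truth.subpop_freq[1])
        assert np.nanmean(fst) == pytest.approx(0.0, abs=1e-12)

    def test_divergence_calibration(self):
        cfg = neutral_cfg(seed=3, n_loci=20_000, divergence_fst=0.02)
        truth = draw_truth(cfg)
        fst = pairwise_fst(truth.subpop_freq[0], truth.subpop_freq[1])
        assert np.nanmean(fst) == pytest.approx(0.02, rel=0.15)

    def test_hardy_weinberg_proportions(self):
        """Genotype counts at n=10^4 match HW expectations (chi-square GOF,
        checked per subpopulation at a handful of loci)."""
        cfg = neutral_cfg(seed=5, n_loci=12, n_sown=10_000, divergence_fst=0.01)
        rng = np.random.default_rng(cfg.seed)
        truth = draw_truth(cfg, rng)
        g = sample_cohort(truth, cfg.n_sown, cfg, rng, "pop")
        labels = truth.subpop_labels["pop"]
        for k in (0, 1):
            rows = labels == k
            n = rows.sum()
            for j in range(5):
                q = truth.subpop_freq[k, j]
                expected = n * np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])
                observed = np.array([(g.dosage[rows, j] == d).sum() for d in (0, 1, 2)])
                chi2 = ((observed - expected) ** 2 / expected).sum()
                assert stats.chi2.sf(chi2, df=2) > 1e-4  # not grossly non-HW


class TestViabilitySelection:
    def test_single_locus_closed_form_example(self):
        # q = 0.5 with survival (0.5, 0.75, 1.0): q' = 0.4375 / 0.75
        assert expected_post_selection_freq(0.5, (0.5, 0.75, 1.0)) == pytest.approx(
            0.583333, abs=1e-6
        )

    def test_mc_mean_matches_closed_form(self):
        cfg = neutral_cfg(seed=8, n_loci=5, n_sown=2000, n_survivors=500,
                          divergence_fst=0.0, base_freq_range=(0.5, 0.5))
        rng = np.random.default_rng(cfg.seed)
        truth = draw_truth(cfg, rng)
        probs = {0: (0.5, 0.75, 1.0)}
        qs = []
        for _ in range(200):
            cohort = sample_cohort(truth, cfg.n_sown, cfg, rng, "p")
            surv = apply_viability_selection(cohort, cfg, rng, survival=probs)
            qs.append(surv.dosage[:, 0].mean() / 2)
        qs = np.array(qs)
        se = qs.std(ddof=1) / np.sqrt(len(qs))
        assert abs(qs.mean() - 0.583333) < 3 * se

    def test_neutral_changes_are_drift_sized(self):
        cfg = neutral_cfg(seed=9, n_loci=300, n_sown=2000, n_survivors=500)
        rng = np.random.default_rng(cfg.seed)
        truth = draw_truth(cfg, rng)
        cohort = sample_cohort(truth, cfg.n_sown, cfg, rng, "p")
        surv = apply_viability_selection(cohort, cfg, rng, survival={})
        q0 = cohort.dosage.mean(axis=0) / 2
        q1 = surv.dosage.mean(axis=0) / 2
        drift_sd = np.sqrt(q0 * (1 - q0) / (2 * surv.n_individuals))
        z = (q1 - q0) / drift_sd
        assert abs(z.mean()) < 0.2
        assert np.abs(z).max() < 6

    def test_expected_survivor_count(self):
        cfg = neutral_cfg(seed=10, n_loci=50, n_sown=4000, n_survivors=1000)
        rng = np.random.default_rng(cfg.seed)
        truth = draw_truth(cfg, rng)
        counts = []
        for _ in range(30):
            cohort = sample_cohort(truth, cfg.n_sown, cfg, rng, "p")
            counts.append(apply_viability_selection(cohort, cfg, rng, survival={}).n_individuals)
        assert np.mean(counts) == pytest.approx(1000, rel=0.05)

    def test_all_zero_weights_rejected(self):
        cfg = neutral_cfg(seed=1, n_loci=5, n_sown=50, n_survivors=10)
        rng = np.random.default_rng(0)
        truth = draw_truth(cfg, rng)
        cohort = sample_cohort(truth, 50, cfg, rng, "p")
        with pytest.raises(ValueError, match="zero"):
            apply_viability_selection(cohort, cfg, rng, survival={0: (0.0, 0.0, 0.0)})


class TestGbsReads:
    def test_no_error_hom_ref_has_no_alt_reads(self):
        cfg = neutral_cfg(seed=2, n_loci=40, seq_error=0.0)
        rng = np.random.default_rng(1)
        truth = draw_truth(cfg, rng)
        g = sample_cohort(truth, 50, cfg, rng, "p")
        g.dosage[:] = 0
        reads = simulate_gbs_reads(g, cfg, rng)
        assert (reads.depth_alt == 0).all()
        called = reads.dosage != MISSING
        assert (reads.dosage[called] == 0).all()

    def test_low_depth_means_mostly_missing_after_filter(self):
        cfg = neutral_cfg(seed=2, n_loci=40, gbs_depth_mean=1.0)
        rng = np.random.default_rng(1)
        truth = draw_truth(cfg, rng)
        g = sample_cohort(truth, 60, cfg, rng, "p")
        reads = simulate_gbs_reads(g, cfg, rng)
        filtered = filter_genotype_calls(reads, FilterConfig())
        assert (filtered.dosage == MISSING).mean() > 0.9

    def test_recalled_frequencies_unbiased_at_decent_depth(self):
        cfg = neutral_cfg(seed=6, n_loci=400, gbs_depth_mean=30.0)
        rng = np.random.default_rng(cfg.seed)
        truth = draw_truth(cfg, rng)
        g = sample_cohort(truth, 300, cfg, rng, "p")
        true_q = g.dosage.mean(axis=0) / 2
        reads = filter_genotype_calls(simulate_gbs_reads(g, cfg, rng))
        called = reads.dosage != MISSING
        est_q = np.where(called, reads.dosage, 0).sum(axis=0) / (2 * called.sum(axis=0))
        bias = (est_q - true_q).mean()
        assert abs(bias) < 0.005


class TestPoolReads:
    def sample(self, seed=12, n=100, L=300, **kw):
        cfg = neutral_cfg(seed=seed, n_loci=L, **kw)
        rng = np.random.default_rng(seed)
        truth = draw_truth(cfg, rng)
        return cfg, rng, sample_cohort(truth, n, cfg, rng, "p")

    def test_equal_weights_high_depth_recovers_sample_frequency(self):
        cfg, rng, g = self.sample(pool_depth_mean=50_000.0, seq_error=0.0,
                                  high_depth_cutoff=10**9)
        p = simulate_pool_reads(g, cfg, mode="dna_pool", rng=rng)
        qhat = p.counts_alt[0] / p.depth[0]
        true_q = g.dosage.mean(axis=0) / 2
        assert np.abs(qhat - true_q).mean() < 0.005

    def test_concentrated_leaf_pool_converges_to_dna_pool(self):
        cfg, rng, g = self.sample(pool_concentration=1e7, seq_error=0.0,
                                  high_depth_cutoff=10**9)
        reps = 20
        leaf = simulate_pool_reads(g, cfg, mode="leaf_pool", n_replicates=reps, rng=rng)
        dna = simulate_pool_reads(g, cfg, mode="dna_pool", n_replicates=reps, rng=rng)
        sd_leaf = (leaf.counts_alt / leaf.depth).std(axis=0).mean()
        sd_dna = (dna.counts_alt / dna.depth).std(axis=0).mean()
        assert sd_leaf == pytest.approx(sd_dna, rel=0.15)

    def test_leaf_pool_noisier_than_dna_pool_at_matched_depth(self):
        cfg, rng, g = self.sample(pool_concentration=1.0, high_depth_cutoff=10**9)
        reps = 30
        leaf = simulate_pool_reads(g, cfg, mode="leaf_pool", n_replicates=reps, rng=rng)
        dna = simulate_pool_reads(g, cfg, mode="dna_pool", n_replicates=reps, rng=rng)

        def rep_dev(t):
            q = t.counts_alt / np.maximum(t.depth, 1)
            return np.abs(q[::2] - q[1::2]).mean()  # replicate-vs-replicate

        assert rep_dev(leaf) > rep_dev(dna)

    def test_replicate_count_validated(self):
        cfg, rng, g = self.sample()
        with pytest.raises(ValueError):
            simulate_pool_reads(g, cfg, n_replicates=0, rng=rng)
        with pytest.raises(ValueError):
            simulate_pool_reads(g, cfg, mode="nonsense", rng=rng)


class TestStudyDesigns:
    def test_study1_determinism(self):
        cfg = SimConfig(seed=31, n_loci=120)
        a = simulate_study1(cfg)
        b = simulate_study1(cfg)
        np.testing.assert_array_equal(a.genotypes.dosage, b.genotypes.dosage)
        np.testing.assert_array_equal(a.genotypes.depth_alt, b.genotypes.depth_alt)

    def test_study1_layout(self):
        cfg = SimConfig(seed=31, n_loci=80)
        s1 = simulate_study1(cfg)
        pops = s1.genotypes.population_ids
        assert pops == ["orig", "S1", "S2", "S3", "S4"]
        assert sum(1 for _, p in s1.genotypes.individuals if p == "orig") == 88
        assert sum(1 for _, p in s1.genotypes.individuals if p == "S1") == 48

    def test_study3_layout_and_replicates(self):
        cfg = SimConfig(seed=31, n_loci=80)
        s3 = simulate_study3(cfg)
        assert s3.pool_counts.n_pools == 12  # 3+3 replicates on PsH, 1 elsewhere
        plots = sorted(set(s3.groups.values()))
        assert plots == ["MsH1", "MsH2", "MsL1", "MsL2", "PsH1", "PsH2", "PsL1", "PsL2"]
        assert s3.design["PsH1"] == ("pure", "high")
        assert s3.design["MsL2"] == ("mixed", "low")

    def test_selection_shifts_match_structured_expectation_direction(self):
        """Every selected locus default is selected upward; with heavy random
        mortality the realized mean shift is positive, bounded by the
        single-locus expectation (multi-locus load attenuates it)."""
        cfg = SimConfig(seed=41, n_loci=400)
        s1 = simulate_study1(cfg, with_reads=False)
        sel = s1.truth.selected_indices
        surv_rows = [i for i, (_, p) in enumerate(s1.genotypes.individuals) if p != "orig"]
        q_surv = s1.genotypes.dosage[surv_rows][:, sel].mean(axis=0) / 2
        shift = q_surv - s1.truth.base_freq[sel]
        exp_shift = np.array(
            [s1.truth.expected_post_freq[int(j)] for j in sel]
        ) - s1.truth.base_freq[sel]
        assert shift.mean() > 0.04
        assert shift.mean() < exp_shift.mean() + 0.02
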