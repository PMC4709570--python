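import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from sexconn import (bh_adjust, fisher_meta, median_fold_change, sex_de,
                     sex_chromosome_enrichment, tumor_vs_normal_de,
                     wilcoxon_rank_sum)
from sexconn.diffexp import pan_cancer_meta


class TestWilcoxonRankSum:
    def test_exact_two_vs_two(self):
        w, p = wilcoxon_rank_sum([1, 2], [3, 4], mode="exact")
        assert w == 3.0
        assert p == pytest.approx(2 / 6, abs=1e-12)

    def test_all_tied_values_give_p_one(self):
        _, p = wilcoxon_rank_sum([5, 5, 5], [5, 5, 5])
        assert p == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0, 2.0])

    def test_exact_mode_refuses_ties(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([1, 1], [2, 3], mode="exact")

    @pytest.mark.parametrize("n1,n2", [(n1, n2) for n1 in range(1, 7)
                                       for n2 in range(n1, 7)])
    def test_exact_matches_enumeration(self, n1, n2):
        rng = np.random.default_rng(100 * n1 + n2)
        for _ in range(5):
            x = rng.normal(size=n1)
            y = rng.normal(size=n2)
            _, p = wilcoxon_rank_sum(x, y, mode="exact")
            assert p == pytest.approx(
                oracles.wilcoxon_exact_by_enumeration(x, y), abs=1e-12)

    def test_approx_close_to_exact_for_moderate_groups(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=9)
        y = rng.normal(1.0, 1.0, size=9)
        _, p_exact = wilcoxon_rank_sum(x, y, mode="exact")
        _, p_approx = wilcoxon_rank_sum(x, y, mode="approx")
        assert p_approx == pytest.approx(p_exact, rel=0.2, abs=0.02)


class TestBHAdjust:
    def test_hand_computed_stepup(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx(
            [0.03, 0.03, 0.03])

    def test_single_test_identity(self):
        assert bh_adjust([0.123]) == pytest.approx([0.123])

    def test_matches_stepup_oracle_on_random_vectors(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            p = rng.uniform(size=rng.integers(1, 60))
            assert np.max(np.abs(bh_adjust(p) - oracles.bh_stepup(p))) < 1e-12

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20),
           st.data())
    def test_dominates_input_and_is_monotone(self, p, data):
        p = np.asarray(p)
        adj = bh_adjust(p)
        assert np.all(adj >= p - 1e-15)
        assert np.all((adj >= 0) & (adj <= 1))
        # raising one raw p never lowers any adjusted value
        i = data.draw(st.integers(0, len(p) - 1))
        bumped = p.copy()
        bumped[i] = data.draw(st.floats(float(p[i]), 1.0))
        assert np.all(bh_adjust(bumped) >= adj - 1e-12)


class TestMedianFoldChange:
    def test_basic_ratio(self):
        assert median_fold_change([4, 4, 4], [2, 2, 2], 1e-12) == \
            pytest.approx(2.0)

    def test_identical_groups(self):
        assert median_fold_change([3, 7, 5], [3, 7, 5]) == pytest.approx(1.0)

    def test_pseudocount_guards_zero_median(self):
        assert median_fold_change([9, 9, 9], [0, 0, 0], 1.0) == \
            pytest.approx(10.0)


class TestFisherMeta:
    def test_closed_form_for_two_halves(self):
        # X = -2*2*ln(0.5) = 2.7726; df=4 tail = exp(-X/2)*(1+X/2)
        assert fisher_meta([0.5, 0.5]) == pytest.approx(0.5966, abs=1e-4)

    def test_single_p_identity(self):
        assert fisher_meta([0.25]) == pytest.approx(0.25, abs=1e-12)

    def test_permutation_invariance(self):
        assert fisher_meta([0.01, 0.9]) == pytest.approx(
            fisher_meta([0.9, 0.01]), abs=1e-15)

    def test_monotone_in_each_input(self):
        base = fisher_meta([0.2, 0.4, 0.6])
        assert fisher_meta([0.1, 0.4, 0.6]) < base

    def test_zero_raises_unless_clamped(self):
        with pytest.raises(ValueError):
            fisher_meta([0.0, 0.5])
        assert 0 <= fisher_meta([0.0, 0.5], zero_policy="clamp") < 1e-100


class TestCohortLevelDE:
    def test_sex_de_recovers_planted_genes(self, four_arm_cohort):
        table, summary = sex_de(four_arm_cohort)
        planted = four_arm_cohort.genes.query("sex_de").index
        assert (table.loc[planted, "significant"]).mean() >= 0.9
        assert summary["ratio"] == summary["n_significant"] / 30

    def test_sex_de_invariant_to_monotone_transform(self, four_arm_cohort):
        table, _ = sex_de(four_arm_cohort)
        warped = four_arm_cohort.matrix ** 1.7  # strictly monotone on [0, inf)
        from sexconn import ExpressionDataset
        warped_ds = ExpressionDataset(warped, four_arm_cohort.samples,
                                      four_arm_cohort.genes)
        table_w, _ = sex_de(warped_ds)
        assert np.allclose(table["p"], table_w["p"])

    def test_tumor_vs_normal_refuses_small_arm(self, four_arm_cohort):
        with pytest.raises(ValueError, match="male tumor"):
            tumor_vs_normal_de(four_arm_cohort, "male", min_per_arm=20)

    def test_fc_inverts_when_orientation_swapped(self, four_arm_cohort):
        de = tumor_vs_normal_de(four_arm_cohort, "male",
                                pseudocount=1e-9)
        flipped = four_arm_cohort.samples.copy()
        flipped["tissue"] = flipped["tissue"].map(
            {"tumor": "normal", "normal": "tumor"})
        from sexconn import ExpressionDataset
        ds = ExpressionDataset(four_arm_cohort.matrix, flipped,
                               four_arm_cohort.genes)
        de_flip = tumor_vs_normal_de(ds, "male", pseudocount=1e-9)
        assert np.allclose(de["fc"] * de_flip["fc"], 1.0, rtol=1e-6)

    def test_male_only_effects_absent_from_female_run(self, four_arm_cohort):
        male_de = tumor_vs_normal_de(four_arm_cohort, "male")
        female_de = tumor_vs_normal_de(four_arm_cohort, "female")
        male_only = four_arm_cohort.genes.query(
            "tumor_de_class == 'male_only'").index
        assert male_de.loc[male_only, "significant"].mean() >= 0.8
        assert female_de.loc[male_only, "significant"].mean() <= 0.2


class TestSexChromosomeEnrichment:
    def test_matches_fisher_exact_oracle(self, four_arm_cohort):
        # 8 of 10 significant genes on sex chromosomes vs 20 of 300 overall
        genes = four_arm_cohort.genes
        sex_genes = list(genes.index[genes.chromosome != "autosome"][:8])
        auto_genes = list(genes.index[genes.chromosome == "autosome"][:2])
        _, _, p = sex_chromosome_enrichment(sex_genes + auto_genes,
                                            four_arm_cohort, method="fisher")
        # condition on the 2x2 margins and enumerate the hypergeometric tail
        k, n = 8, 10
        big_k = int((genes.chromosome != "autosome").sum())
        big_n = len(genes)
        # Fisher's exact two-sided p: sum of tables at most as probable
        from scipy.stats import hypergeom
        total_sex = k + big_k
        total = n + big_n
        dist = hypergeom(total, total_sex, n)
        p_obs = dist.pmf(k)
        expected = sum(dist.pmf(i) for i in range(0, n + 1)
                       if dist.pmf(i) <= p_obs * (1 + 1e-10))
        assert p == pytest.approx(expected, abs=1e-10)

    def test_extreme_concentration_is_significant(self, four_arm_cohort):
        genes = four_arm_cohort.genes
        sig = list(genes.index[genes.chromosome != "autosome"])
        prop_sig, prop_bg, p = sex_chromosome_enrichment(sig, four_arm_cohort)
        assert prop_sig == 1.0
        assert p < 1e-6

    def test_empty_significant_set_flagged(self, four_arm_cohort):
        with pytest.raises(ValueError):
            sex_chromosome_enrichment([], four_arm_cohort)


class TestPanCancerMeta:
    def test_single_cohort_reduces_to_identity(self):
        table = pd.DataFrame({"p": [0.01, 0.5], "fc": [2.0, 0.5]},
                             index=["g1", "g2"])
        meta = pan_cancer_meta([table])
        assert np.allclose(meta["p"], table["p"], atol=1e-12)
        assert np.allclose(meta["fc"], table["fc"])

    def test_opposite_fold_changes_cancel(self):
        t1 = pd.DataFrame({"p": [0.5], "fc": [4.0]}, index=["g"])
        t2 = pd.DataFrame({"p": [0.5], "fc": [0.25]}, index=["g"])
        assert pan_cancer_meta([t1, t2])["fc"].iloc[0] == pytest.approx(1.0)
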