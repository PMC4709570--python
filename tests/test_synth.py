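import numpy as np
import pytest

from sexconn import (CohortConfig, LibraryConfig, generate_cohort,
                     generate_library, score_library, sex_de)
from sexconn.signatures import SignaturePair


def null_config(seed=0, **overrides):
    base = dict(n_genes=200, n_autosomal=200, n_x=0, n_y=0,
                n_male_tumor=20, n_female_tumor=20,
                n_male_normal=20, n_female_normal=20, seed=seed)
    base.update(overrides)
    return CohortConfig(**base)


class TestCohortConfigValidation:
    def test_partition_must_sum(self):
        with pytest.raises(ValueError, match="partition"):
            CohortConfig(n_genes=10, n_autosomal=5, n_x=4, n_y=2,
                         n_male_tumor=5, n_female_tumor=5,
                         n_male_normal=0, n_female_normal=0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            null_config(n_male_tumor=-1, n_genes=200)

    def test_effect_size_must_exceed_one(self):
        with pytest.raises(ValueError, match="effect_size"):
            null_config(effect_size=0.5)

    def test_planted_genes_bounded_by_autosomal_pool(self):
        with pytest.raises(ValueError, match="planted"):
            null_config(n_sex_de=150, n_tumor_de_shared=100)


class TestGenerateCohort:
    def test_seeded_determinism(self):
        cfg = null_config(seed=7, n_sex_de=10)
        a = generate_cohort(cfg)
        b = generate_cohort(cfg)
        assert (a.matrix.values == b.matrix.values).all()
        assert a.genes.equals(b.genes)

    def test_null_cohort_controls_false_discoveries(self):
        table, summary = sex_de(generate_cohort(null_config(seed=3)))
        # no planted sex effect: BH < 0.05 calls stay near zero
        assert summary["n_significant"] <= 0.05 * len(table)

    def test_planted_sex_de_recovered(self):
        cfg = CohortConfig(n_genes=300, n_autosomal=280, n_x=10, n_y=10,
                           n_male_tumor=40, n_female_tumor=40,
                           n_male_normal=40, n_female_normal=40,
                           n_sex_de=50, effect_size=4.0, seed=21)
        cohort = generate_cohort(cfg)
        table, _ = sex_de(cohort)
        planted = cohort.genes.query("sex_de").index
        assert int(table.loc[planted, "significant"].sum()) >= 45

    def test_y_genes_silent_in_females(self):
        cohort = generate_cohort(null_config(
            n_genes=200, n_autosomal=180, n_x=10, n_y=10, seed=4))
        y_rows = cohort.genes.chromosome == "Y"
        female = cohort.sample_mask(sex="female")
        male = cohort.sample_mask(sex="male")
        vals = cohort.matrix.to_numpy()
        assert vals[np.ix_(y_rows.to_numpy(), female)].mean() < \
            0.05 * vals[np.ix_(y_rows.to_numpy(), male)].mean()

    def test_xist_divergent_in_tumors_not_normals_by_default(self):
        cohort = generate_cohort(null_config(
            n_genes=200, n_autosomal=190, n_x=10, n_y=0, seed=5))
        xist = cohort.genes.index[cohort.genes.is_xist_like][0]
        row = cohort.matrix.loc[xist]
        sams = cohort.samples
        ft = row[(sams.sex == "female") & (sams.tissue == "tumor")].median()
        mt = row[(sams.sex == "male") & (sams.tissue == "tumor")].median()
        fn = row[(sams.sex == "female") & (sams.tissue == "normal")].median()
        mn = row[(sams.sex == "male") & (sams.tissue == "normal")].median()
        assert ft / mt > 20            # strongly female-high in tumors
        assert 0.5 < fn / mn < 2.0     # sex-concordant in normals

    def test_xist_divergence_everywhere_when_disabled(self):
        cohort = generate_cohort(null_config(
            n_genes=200, n_autosomal=190, n_x=10, n_y=0, seed=5,
            xist_tumor_divergent=False))
        xist = cohort.genes.index[cohort.genes.is_xist_like][0]
        row = cohort.matrix.loc[xist]
        sams = cohort.samples
        fn = row[(sams.sex == "female") & (sams.tissue == "normal")].median()
        mn = row[(sams.sex == "male") & (sams.tissue == "normal")].median()
        assert fn / mn > 20


def _toy_signatures(universe):
    male = SignaturePair(universe[:5], universe[5:10], "male", size_cap=5)
    female = SignaturePair(universe[10:15], universe[15:20], "female",
                           size_cap=5)
    return {"male": male, "female": female}


class TestGenerateLibrary:
    def test_seeded_determinism(self):
        cohort = generate_cohort(null_config(seed=1))
        sigs = _toy_signatures(cohort.gene_ids)
        cfg = LibraryConfig(n_perturbagens=10, planted=(("a", "I"),), seed=9)
        lib1 = generate_library(cfg, sigs, cohort.gene_ids)
        lib2 = generate_library(cfg, sigs, cohort.gene_ids)
        assert (lib1.ranks.values == lib2.ranks.values).all()

    def test_profiles_are_complete_rankings(self):
        cohort = generate_cohort(null_config(seed=1))
        sigs = _toy_signatures(cohort.gene_ids)
        lib = generate_library(LibraryConfig(n_perturbagens=5, seed=2),
                               sigs, cohort.gene_ids)
        expected = np.arange(1, lib.n_genes + 1)
        assert all((np.sort(lib.ranks[c].to_numpy()) == expected).all()
                   for c in lib.ranks.columns)

    def test_zero_mimic_strength_removes_planted_signal(self):
        cohort = generate_cohort(null_config(seed=1))
        sigs = _toy_signatures(cohort.gene_ids)
        cfg = LibraryConfig(n_perturbagens=40,
                            planted=(("p1", "III"),), mimic_strength=0.0,
                            seed=3)
        lib = generate_library(cfg, sigs, cohort.gene_ids)
        targeted = lib.ranks.loc[sigs["male"].sensitivity,
                                 lib.manifest.index[
                                     lib.manifest.perturbagen == "p1"]]
        # targeted genes sit at unremarkable ranks
        mid = (lib.n_genes + 1) / 2
        se = lib.n_genes / np.sqrt(12 * targeted.size)
        assert abs(targeted.to_numpy().mean() - mid) < 4 * se

    def test_full_mimic_type_three_tops_both_queries(self):
        cohort = generate_cohort(null_config(seed=1))
        sigs = _toy_signatures(cohort.gene_ids)
        cfg = LibraryConfig(n_perturbagens=500, n_replicates_per_perturbagen=2,
                            planted=(("strong", "III"),), mimic_strength=1.0,
                            seed=13)
        lib = generate_library(cfg, sigs, cohort.gene_ids)
        for sex in ("male", "female"):
            scores = score_library(lib, up_set=sigs[sex].sensitivity,
                                   down_set=sigs[sex].resistance)
            assert scores.loc["strong", "score"] >= 99.0

    def test_missing_signature_genes_reported(self):
        cohort = generate_cohort(null_config(seed=1))
        sigs = _toy_signatures(cohort.gene_ids)
        with pytest.raises(ValueError, match="absent"):
            generate_library(LibraryConfig(n_perturbagens=5),
                             sigs, cohort.gene_ids[:10])

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            LibraryConfig(n_perturbagens=5, mimic_strength=1.5)
        with pytest.raises(ValueError):
            LibraryConfig(n_perturbagens=0)
        with pytest.raises(ValueError):
            LibraryConfig(n_perturbagens=5, planted=(("a", "IV"),))
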