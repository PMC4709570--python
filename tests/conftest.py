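from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from sexconn import CohortConfig, ExpressionDataset, generate_cohort


@pytest.fixture(scope="session")
def four_arm_cohort() -> ExpressionDataset:
    """Mixed cohort: sex chromosomes, planted sex-DE and tumor-DE effects."""
    config = CohortConfig(
        n_genes=300, n_autosomal=280, n_x=15, n_y=5,
        n_male_tumor=15, n_female_tumor=15,
        n_male_normal=15, n_female_normal=15,
        n_sex_de=20, n_tumor_de_shared=30,
        n_tumor_de_male_only=15, n_tumor_de_female_only=15,
        effect_size=4.0, dispersion=0.5, seed=101)
    return generate_cohort(config)


@pytest.fixture()
def tiny_dataset() -> ExpressionDataset:
    """Hand-built 4-gene x 8-sample dataset for interface tests."""
    rng = np.random.default_rng(0)
    genes = pd.DataFrame(
        {"chromosome": ["autosome", "autosome", "X", "Y"]},
        index=pd.Index([f"g{i}" for i in range(4)], name="gene_id"))
    samples = pd.DataFrame(
        {"sex": ["male"] * 4 + ["female"] * 4,
         "tissue": ["tumor", "tumor", "normal", "normal"] * 2},
        index=pd.Index([f"s{i}" for i in range(8)], name="sample_id"))
    matrix = pd.DataFrame(rng.gamma(2.0, 10.0, size=(4, 8)),
                          index=genes.index, columns=samples.index)
    return ExpressionDataset(matrix, samples, genes, cancer_label="TOY")
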