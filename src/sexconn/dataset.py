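"""Expression cohort container: a gene x sample matrix with per-sample sex
and tissue labels and per-gene chromosome annotations.

The container is deliberately thin — a validated bundle of three aligned
pandas objects — because every analysis in the package is rank- or
label-based and operates directly on the matrix values.
"""

from __future__ import annotations

import os
from collections.abc import Sequence

import numpy as np
import pandas as pd

from . import io

SEXES = ("male", "female")
TISSUES = ("tumor", "normal")
CHROMOSOMES = ("autosome", "X", "Y")
SEX_CHROMOSOMES = ("X", "Y")


class ExpressionDataset:
    """Nonnegative normalized expression with sex/tissue/chromosome labels.

    Parameters
    ----------
    matrix
        Gene x sample DataFrame of nonnegative normalized expression values
        (RNA-seq normalized counts or similar).
    samples
        DataFrame indexed by sample id with at least columns ``sex``
        (male/female) and ``tissue`` (tumor/normal), aligned to the matrix
        columns.
    genes
        DataFrame indexed by gene id with at least a ``chromosome`` column
        (autosome/X/Y), aligned to the matrix rows. Extra columns (e.g.
        simulation ground truth) are carried along untouched.
    cancer_label
        Free-text cohort label (e.g. a tumor-type abbreviation).
    """

    def __init__(self, matrix: pd.DataFrame, samples: pd.DataFrame,
                 genes: pd.DataFrame, cancer_label: str = "") -> None:
        matrix = pd.DataFrame(matrix)
        if not matrix.index.is_unique:
            raise ValueError("gene ids must be unique")
        if not matrix.columns.is_unique:
            raise ValueError("sample ids must be unique")
        if not matrix.index.equals(pd.Index(genes.index)):
            raise ValueError("gene annotation index must match matrix rows")
        if not matrix.columns.equals(pd.Index(samples.index)):
            raise ValueError("sample annotation index must match matrix columns")
        values = matrix.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValueError("expression values must be finite")
        if (values < 0).any():
            raise ValueError("expression values must be nonnegative")
        for col, allowed in (("sex", SEXES), ("tissue", TISSUES)):
            if col not in samples:
                raise ValueError(f"samples table lacks required column {col!r}")
            bad = set(samples[col]) - set(allowed)
            if bad:
                raise ValueError(f"invalid {col} labels: {sorted(bad)}")
        if "chromosome" not in genes:
            raise ValueError("genes table lacks required column 'chromosome'")
        bad = set(genes["chromosome"]) - set(CHROMOSOMES)
        if bad:
            raise ValueError(f"invalid chromosome labels: {sorted(bad)}")
        self.matrix = matrix.astype(float)
        self.samples = samples.copy()
        self.genes = genes.copy()
        self.cancer_label = cancer_label

    # -- basic views ------------------------------------------------------

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def sample_sex(self) -> pd.Series:
        return self.samples["sex"]

    @property
    def sample_tissue(self) -> pd.Series:
        return self.samples["tissue"]

    def sample_mask(self, sex: str | None = None,
                    tissue: str | None = None) -> np.ndarray:
        mask = np.ones(self.n_samples, dtype=bool)
        if sex is not None:
            mask &= (self.samples["sex"] == sex).to_numpy()
        if tissue is not None:
            mask &= (self.samples["tissue"] == tissue).to_numpy()
        return mask

    def subset(self, sex: str | None = None,
               tissue: str | None = None) -> "ExpressionDataset":
        mask = self.sample_mask(sex=sex, tissue=tissue)
        return ExpressionDataset(self.matrix.loc[:, mask],
                                 self.samples.loc[mask],
                                 self.genes, self.cancer_label)

    def with_sample_sex(self, sex_labels: Sequence[str]) -> "ExpressionDataset":
        """Return a copy with sex labels replaced (tissue untouched)."""
        if len(sex_labels) != self.n_samples:
            raise ValueError("need one sex label per sample")
        samples = self.samples.copy()
        samples["sex"] = list(sex_labels)
        return ExpressionDataset(self.matrix, samples, self.genes,
                                 self.cancer_label)

    # -- persistence ------------------------------------------------------

    def write(self, prefix: str | os.PathLike) -> None:
        """Write ``<prefix>.gct`` plus sample/gene annotation TSV sidecars."""
        prefix = str(prefix)
        io.write_gct(self.matrix, prefix + ".gct",
                     descriptions=self.genes["chromosome"])
        io.write_tsv(self.samples, prefix + ".samples.tsv", float_format=None)
        io.write_tsv(self.genes, prefix + ".genes.tsv", float_format=None)

    @classmethod
    def read(cls, prefix: str | os.PathLike,
             cancer_label: str = "") -> "ExpressionDataset":
        prefix = str(prefix)
        matrix, _ = io.read_gct(prefix + ".gct")
        samples = io.read_tsv(prefix + ".samples.tsv")
        genes = io.read_tsv(prefix + ".genes.tsv")
        return cls(matrix, samples, genes, cancer_label)
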