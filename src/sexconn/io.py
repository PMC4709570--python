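"""Readers and writers for the small tab-delimited formats used throughout.

GCT (expression / rank matrices) and GMT (named gene sets) are the two
community conventions the package speaks; both are plain text and small
enough that a direct pandas round-trip is the simplest faithful treatment.
"""

from __future__ import annotations

import os
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd

GCT_VERSION = "#1.2"


def write_gct(matrix: pd.DataFrame, path: str | os.PathLike,
              descriptions: pd.Series | None = None) -> None:
    """Write a gene x sample DataFrame as a GCT 1.2 file.

    ``descriptions`` fills the Description column (gene ids are reused when
    absent).
    """
    desc = descriptions.reindex(matrix.index) if descriptions is not None \
        else pd.Series(matrix.index, index=matrix.index)
    with open(path, "w") as fh:
        fh.write(f"{GCT_VERSION}\n")
        fh.write(f"{matrix.shape[0]}\t{matrix.shape[1]}\n")
        fh.write("Name\tDescription\t" + "\t".join(map(str, matrix.columns)) + "\n")
        for gene, row in matrix.iterrows():
            fh.write(str(gene) + "\t" + str(desc.loc[gene]) + "\t"
                     + "\t".join(_cell(v) for v in row.to_numpy()) + "\n")


def _cell(value) -> str:
    # 17 significant digits round-trips IEEE doubles exactly
    if isinstance(value, (float, np.floating)):
        return format(float(value), ".17g")
    return str(value)


def read_gct(path: str | os.PathLike) -> tuple[pd.DataFrame, pd.Series]:
    """Read a GCT 1.2 file; returns (matrix, description series)."""
    with open(path) as fh:
        version = fh.readline().strip()
        if version != GCT_VERSION:
            raise ValueError(f"unsupported GCT version line: {version!r}")
        n_genes, n_samples = (int(v) for v in fh.readline().split())
        table = pd.read_csv(fh, sep="\t", index_col=0)
    desc = table["Description"]
    matrix = table.drop(columns="Description")
    if matrix.shape != (n_genes, n_samples):
        raise ValueError(
            f"GCT header promises {(n_genes, n_samples)}, file holds {matrix.shape}")
    return matrix, desc


def write_gmt(gene_sets: Mapping[str, Sequence[str]], path: str | os.PathLike,
              descriptions: Mapping[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([str(name), str(desc), *map(str, genes)]) + "\n")


def read_gmt(path: str | os.PathLike) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2 or not fields[0]:
                continue
            sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def write_tsv(table: pd.DataFrame, path: str | os.PathLike,
              float_format: str | None = "%.4f", index: bool = True) -> None:
    table.to_csv(path, sep="\t", float_format=float_format, index=index)


def read_tsv(path: str | os.PathLike, index_col: int | None = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)
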