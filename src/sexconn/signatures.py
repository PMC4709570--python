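"""Sensitivity / resistance signature construction.

From a sex-stratified tumor-vs-normal differential-expression table, the
resistance signature collects the most tumor-overexpressed significant
genes (largest tumor/normal fold change) and the sensitivity signature the
most normal-overexpressed significant genes (smallest tumor/normal fold
change), each capped at 250 genes by default. The pair is used as the
down/up query of a connectivity-map search: reversing the tumor state
means up-regulating the sensitivity set and down-regulating the resistance
set.
"""

from __future__ import annotations

import logging
from collections.abc import Sequence
from dataclasses import dataclass

import pandas as pd

from . import diffexp

logger = logging.getLogger(__name__)

DEFAULT_SIZE_CAP = 250


@dataclass
class SignaturePair:
    """One sex's query pair: up = sensitivity genes, down = resistance genes."""

    sensitivity: list[str]
    resistance: list[str]
    sex: str = ""
    cancer_label: str = ""
    size_cap: int = DEFAULT_SIZE_CAP

    def __post_init__(self) -> None:
        if len(self.sensitivity) > self.size_cap or len(self.resistance) > self.size_cap:
            raise ValueError("signature exceeds its size cap")
        if set(self.sensitivity) & set(self.resistance):
            raise ValueError("sensitivity and resistance sets must be disjoint")

    @property
    def is_empty(self) -> bool:
        return not self.sensitivity or not self.resistance

    def restrict_to(self, universe: Sequence[str]) -> tuple["SignaturePair", list[str]]:
        """Drop genes absent from ``universe``; returns (new pair, dropped)."""
        allowed = set(universe)
        dropped = [g for g in (*self.sensitivity, *self.resistance)
                   if g not in allowed]
        if dropped:
            logger.warning("%s/%s signature: dropping %d gene(s) absent from "
                           "the library universe", self.cancer_label, self.sex,
                           len(dropped))
        pair = SignaturePair(
            [g for g in self.sensitivity if g in allowed],
            [g for g in self.resistance if g in allowed],
            self.sex, self.cancer_label, self.size_cap)
        return pair, dropped


def _ranked_half(table: pd.DataFrame, side: str, size_cap: int) -> list[str]:
    """Top genes of one fold-change side; deterministic tie-breaking.

    Resistance: fc > 1 sorted by descending fc. Sensitivity: fc < 1 sorted
    by ascending fc. Ties break by smaller BH value, then gene id.
    """
    frame = table.reset_index(names="gene")
    if side == "resistance":
        half = frame[frame["fc"] > 1].sort_values(
            ["fc", "bh", "gene"], ascending=[False, True, True])
    else:
        half = frame[frame["fc"] < 1].sort_values(
            ["fc", "bh", "gene"], ascending=[True, True, True])
    return half["gene"].head(size_cap).tolist()


def build_signatures(de_table: pd.DataFrame, sex: str, cancer_label: str = "",
                     size_cap: int = DEFAULT_SIZE_CAP,
                     alpha: float = diffexp.DEFAULT_ALPHA) -> SignaturePair:
    """Build a sensitivity/resistance pair from one DE table.

    ``de_table`` must carry ``bh`` and ``fc`` (tumor/normal orientation)
    columns indexed by gene. Genes with fc exactly 1 fall on neither side.
    """
    for col in ("bh", "fc"):
        if col not in de_table:
            raise ValueError(f"DE table lacks required column {col!r}")
    sig = de_table[de_table["bh"] < alpha]
    resistance = _ranked_half(sig, "resistance", size_cap)
    sensitivity = _ranked_half(sig, "sensitivity", size_cap)
    if len(sig) == 0:
        logger.warning("%s/%s: no significant genes; empty signature pair",
                       cancer_label, sex)
    else:
        for name, genes in (("sensitivity", sensitivity),
                            ("resistance", resistance)):
            if len(genes) < size_cap:
                logger.warning("%s/%s: only %d %s genes available (cap %d)",
                               cancer_label, sex, len(genes), name, size_cap)
    return SignaturePair(sensitivity, resistance, sex, cancer_label, size_cap)


def build_pan_cancer_signatures(per_cancer_de: Sequence[pd.DataFrame], sex: str,
                                size_cap: int = DEFAULT_SIZE_CAP,
                                alpha: float = diffexp.DEFAULT_ALPHA,
                                ) -> SignaturePair:
    """Pan-cancer pair: Fisher-combined significance, geometric-mean fc."""
    meta = diffexp.pan_cancer_meta(list(per_cancer_de))
    return build_signatures(meta, sex, cancer_label="pan-cancer",
                            size_cap=size_cap, alpha=alpha)


def signatures_to_gmt(pairs: Sequence[SignaturePair]) -> dict[str, list[str]]:
    """GMT-style mapping ``<cancer>_<sex>_{SENS,RES} -> genes``."""
    sets: dict[str, list[str]] = {}
    for pair in pairs:
        stem = f"{pair.cancer_label or 'cohort'}_{pair.sex or 'all'}"
        sets[f"{stem}_SENS"] = list(pair.sensitivity)
        sets[f"{stem}_RES"] = list(pair.resistance)
    return sets
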