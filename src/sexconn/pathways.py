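"""Sex-stratified pathway over-representation analysis.

Enrichment of a pathway among the significant tumor-vs-normal genes of one
sex is tested with the upper-tail hypergeometric probability of the
observed-or-greater overlap. Each pathway is then categorized by the pair
of per-sex p-values as male_only, female_only, both, or neither, and a
cohort is summarized by its discordance proportion: among pathways
significant in at least one sex, the fraction significant in exactly one.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping, Sequence

import pandas as pd
from scipy.stats import hypergeom

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05
CATEGORIES = ("male_only", "female_only", "both", "neither")


def ora(pathway_genes: Iterable[str], significant_genes: Iterable[str],
        universe: Iterable[str]) -> float:
    """Hypergeometric over-representation p-value.

    Probability of drawing at least the observed pathway overlap when
    ``len(significant_genes)`` genes are sampled from the universe without
    replacement. An empty pathway is never enriched (p = 1).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty gene universe")
    pathway = set(pathway_genes)
    sig = set(significant_genes)
    for label, subset in (("pathway", pathway), ("significant", sig)):
        extra = subset - universe
        if extra:
            raise ValueError(f"{label} genes outside universe: "
                             f"{sorted(extra)[:5]}")
    if not pathway:
        return 1.0
    overlap = len(pathway & sig)
    return float(hypergeom.sf(overlap - 1, len(universe), len(pathway),
                              len(sig)))


def classify_pathway_sex(p_male: float, p_female: float,
                         alpha: float = DEFAULT_ALPHA) -> str:
    """Four-way sex-specificity category from the two enrichment p-values.

    A pathway is enriched in a sex when its p-value is below alpha; a
    p-value exactly at alpha counts as not significant.
    """
    for p in (p_male, p_female):
        if not 0.0 <= p <= 1.0:
            raise ValueError("p-values must lie in [0, 1]")
    male_sig = p_male < alpha
    female_sig = p_female < alpha
    if male_sig and female_sig:
        return "both"
    if male_sig:
        return "male_only"
    if female_sig:
        return "female_only"
    return "neither"


def discordance_proportion(n_male_only: int, n_female_only: int,
                           n_both: int) -> float:
    """Fraction of significantly enriched pathways enriched in one sex only."""
    counts = (n_male_only, n_female_only, n_both)
    if any(c < 0 for c in counts):
        raise ValueError("counts must be nonnegative")
    total = sum(counts)
    if total == 0:
        raise ValueError("no significant pathways: proportion undefined")
    return (n_male_only + n_female_only) / total


def analyze_pathways(gene_sets: Mapping[str, Sequence[str]],
                     significant_male: Iterable[str],
                     significant_female: Iterable[str],
                     universe: Iterable[str],
                     alpha: float = DEFAULT_ALPHA,
                     ) -> tuple[pd.DataFrame, dict]:
    """Per-pathway sex-stratified enrichment table and cohort summary."""
    universe = list(universe)
    sig_m = set(significant_male)
    sig_f = set(significant_female)
    rows = []
    for name, genes in gene_sets.items():
        members = [g for g in genes if g in set(universe)]
        if len(members) < len(set(genes)):
            logger.warning("pathway %s: %d gene(s) outside universe dropped",
                           name, len(set(genes)) - len(members))
        p_m = ora(members, sig_m, universe)
        p_f = ora(members, sig_f, universe)
        rows.append((name, p_m, p_f, classify_pathway_sex(p_m, p_f, alpha)))
    table = pd.DataFrame(rows, columns=["pathway", "p_male", "p_female",
                                        "category"]).set_index("pathway")
    counts = table["category"].value_counts()
    n_m = int(counts.get("male_only", 0))
    n_f = int(counts.get("female_only", 0))
    n_b = int(counts.get("both", 0))
    summary = {"n_male_only": n_m, "n_female_only": n_f, "n_both": n_b,
               "discordance_proportion":
                   discordance_proportion(n_m, n_f, n_b)
                   if (n_m + n_f + n_b) else float("nan")}
    return table, summary
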