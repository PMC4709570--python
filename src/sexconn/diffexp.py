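"""Univariate differential-expression statistics.

All hypothesis tests in the pipeline are rank-based: the Wilcoxon rank-sum
test compares expression between two groups of samples, the
Benjamini-Hochberg step-up procedure controls the false discovery rate
across genes, and effect sizes are fold changes of group medians. A
chi-square two-proportion test quantifies sex-chromosome enrichment among
significant genes, and Fisher's method combines per-cohort p-values into
pan-cancer ones.
"""

from __future__ import annotations

import logging
import math
import warnings
from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .dataset import SEX_CHROMOSOMES, ExpressionDataset

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05
DEFAULT_PSEUDOCOUNT = 1.0
EXACT_SIZE_LIMIT = 10  # largest per-group size for the exact null


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum test
# ---------------------------------------------------------------------------

def _rank_sum_null_counts(n1: int, n: int) -> np.ndarray:
    """Number of size-``n1`` subsets of ranks {1..n} attaining each rank sum.

    Classic dynamic program over ranks; ``counts[w]`` is the number of
    subsets whose ranks sum to ``w``.
    """
    max_sum = n1 * n - n1 * (n1 - 1) // 2
    counts = np.zeros((n1 + 1, max_sum + 1), dtype=object)
    counts[0, 0] = 1
    for rank in range(1, n + 1):
        for k in range(min(rank, n1), 0, -1):
            counts[k, rank:] = counts[k, rank:] + counts[k - 1, :-rank or None]
    return counts[n1]


def _exact_rank_sum_p(w: float, n1: int, n2: int) -> float:
    """Two-sided exact p for rank sum ``w`` with no ties.

    Two-sidedness is twice the smaller tail probability, capped at 1; with a
    tie-free null the distribution is symmetric so this equals the
    reflection definition.
    """
    counts = _rank_sum_null_counts(n1, n1 + n2)
    total = math.comb(n1 + n2, n1)
    w_int = int(round(w))
    lo = n1 * (n1 + 1) // 2
    cdf = int(sum(counts[lo:w_int + 1]))
    sf = int(sum(counts[w_int:]))
    return min(1.0, 2.0 * min(cdf, sf) / total)


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float],
                      mode: str = "auto") -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test of group ``x`` against group ``y``.

    Returns ``(W, p)`` where ``W`` is the rank sum of ``x`` in the pooled
    ranking. ``mode`` is one of:

    - ``"exact"``: enumerate the tie-free null distribution (both groups
      must have size <= 10 and no ties may be present);
    - ``"approx"``: normal approximation with tie and continuity correction;
    - ``"auto"``: exact when permitted, otherwise approx.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    w = float(ranks[: x.size].sum())
    if np.ptp(pooled) == 0:
        return w, 1.0
    has_ties = np.unique(pooled).size < pooled.size
    small = x.size <= EXACT_SIZE_LIMIT and y.size <= EXACT_SIZE_LIMIT
    use_exact = mode == "exact" or (mode == "auto" and small and not has_ties)
    if mode == "exact" and has_ties:
        raise ValueError("exact mode requires tie-free data")
    if mode not in ("exact", "approx", "auto"):
        raise ValueError(f"unknown mode {mode!r}")
    if use_exact:
        return w, _exact_rank_sum_p(w, x.size, y.size)
    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             method="asymptotic", use_continuity=True)
    return w, float(res.pvalue)


def _rank_sum_rows(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized normal-approximation rank-sum test along rows.

    ``x`` and ``y`` are gene x sample blocks for the two groups. Rows in
    which every pooled value is identical receive p = 1.
    """
    n1 = x.shape[1]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.mannwhitneyu(x, y, axis=1, alternative="two-sided",
                                 method="asymptotic", use_continuity=True)
    u = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    flat = np.ptp(np.concatenate([x, y], axis=1), axis=1) == 0
    p[flat] = 1.0
    p = np.clip(p, 0.0, 1.0)
    w = u + n1 * (n1 + 1) / 2.0
    return w, p


# ---------------------------------------------------------------------------
# Multiple testing and effect sizes
# ---------------------------------------------------------------------------

def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, order-aligned with input."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if not np.isfinite(p).all() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def median_fold_change(x: Sequence[float], y: Sequence[float],
                       pseudocount: float = DEFAULT_PSEUDOCOUNT) -> float:
    """Fold change of group medians, (median(x)+c) / (median(y)+c)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    return float((np.median(x) + pseudocount) / (np.median(y) + pseudocount))


def fisher_meta(p: Sequence[float], zero_policy: str = "raise") -> float:
    """Fisher's method: combine independent p-values for one hypothesis.

    X = -2 sum(ln p) is referred to a chi-square with 2k degrees of
    freedom. Inputs of exactly zero (attainable for permutation p-values)
    either raise or, with ``zero_policy="clamp"``, are clamped to the
    smallest positive float with a logged warning.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    if (p == 0).any():
        if zero_policy == "clamp":
            logger.warning("fisher_meta: clamping %d zero p-value(s) to tiny",
                           int((p == 0).sum()))
            p = np.maximum(p, np.finfo(float).tiny)
        else:
            raise ValueError("p-value of 0 passed to Fisher's method "
                             "(use zero_policy='clamp' to override)")
    x = -2.0 * np.log(p).sum()
    return float(stats.chi2.sf(x, 2 * p.size))


def _fisher_meta_rows(p: np.ndarray) -> np.ndarray:
    """Row-wise Fisher combination with zero clamping (genes x cohorts)."""
    p = np.maximum(np.asarray(p, dtype=float), np.finfo(float).tiny)
    x = -2.0 * np.log(p).sum(axis=1)
    return stats.chi2.sf(x, 2 * p.shape[1])


# ---------------------------------------------------------------------------
# Cohort-level analyses
# ---------------------------------------------------------------------------

def _de_table(x: np.ndarray, y: np.ndarray, gene_index: pd.Index,
              alpha: float, pseudocount: float) -> pd.DataFrame:
    w, p = _rank_sum_rows(x, y)
    bh = bh_adjust(p)
    fc = (np.median(x, axis=1) + pseudocount) / (np.median(y, axis=1) + pseudocount)
    return pd.DataFrame(
        {"W": w, "p": p, "bh": bh, "fc": fc, "significant": bh < alpha},
        index=gene_index)


def sex_de(dataset: ExpressionDataset, alpha: float = DEFAULT_ALPHA,
           pseudocount: float = DEFAULT_PSEUDOCOUNT,
           ) -> tuple[pd.DataFrame, dict]:
    """Male-vs-female differential expression within tumor samples.

    Returns a per-gene table (W, p, bh, fc, significant; fold change
    oriented male/female) and a summary with the significant-gene count and
    its ratio to the tumor sample size.
    """
    tumors = dataset.subset(tissue="tumor")
    male = tumors.sample_mask(sex="male")
    female = tumors.sample_mask(sex="female")
    if male.sum() < 2 or female.sum() < 2:
        raise ValueError("need at least two tumor samples of each sex")
    values = tumors.matrix.to_numpy()
    table = _de_table(values[:, male], values[:, female],
                      dataset.matrix.index, alpha, pseudocount)
    n_sig = int(table["significant"].sum())
    n_samples = int(tumors.n_samples)
    summary = {"cancer_label": dataset.cancer_label,
               "n_significant": n_sig,
               "sample_size": n_samples,
               "ratio": n_sig / n_samples}
    return table, summary


def tumor_vs_normal_de(dataset: ExpressionDataset, sex: str,
                       alpha: float = DEFAULT_ALPHA,
                       pseudocount: float = DEFAULT_PSEUDOCOUNT,
                       min_per_arm: int = 10) -> pd.DataFrame:
    """Tumor-vs-normal differential expression restricted to one sex.

    Fold changes are oriented tumor/normal. Cohorts with fewer than
    ``min_per_arm`` samples in either arm are refused (mirroring the
    inclusion rule of requiring more than ten cases per arm).
    """
    tumor = dataset.sample_mask(sex=sex, tissue="tumor")
    normal = dataset.sample_mask(sex=sex, tissue="normal")
    for arm, mask in (("tumor", tumor), ("normal", normal)):
        if mask.sum() < min_per_arm:
            raise ValueError(
                f"{sex} {arm} arm has {int(mask.sum())} samples, "
                f"below the floor of {min_per_arm}")
    values = dataset.matrix.to_numpy()
    return _de_table(values[:, tumor], values[:, normal],
                     dataset.matrix.index, alpha, pseudocount)


def sex_chromosome_enrichment(significant_genes: Iterable[str],
                              dataset: ExpressionDataset,
                              method: str = "chi2",
                              ) -> tuple[float, float, float]:
    """Sex-chromosome fraction among significant genes vs. the whole universe.

    Returns ``(prop_significant, prop_background, p)`` where the p-value is
    a two-proportion chi-square test with continuity correction (or
    Fisher's exact test with ``method="fisher"``).
    """
    sig = pd.Index(significant_genes)
    universe = dataset.genes.index
    missing = sig.difference(universe)
    if len(missing):
        raise ValueError(f"significant genes outside universe: {list(missing)[:5]}")
    if len(sig) == 0:
        raise ValueError("empty significant set: proportion undefined")
    on_sex = dataset.genes["chromosome"].isin(SEX_CHROMOSOMES)
    k = int(on_sex.loc[sig].sum())
    n = len(sig)
    big_k = int(on_sex.sum())
    big_n = len(universe)
    table = np.array([[k, n - k], [big_k, big_n - big_k]])
    if method == "chi2":
        res = stats.chi2_contingency(table, correction=True)
        p = float(res.pvalue)
    elif method == "fisher":
        p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    else:
        raise ValueError(f"unknown method {method!r}")
    return k / n, big_k / big_n, p


def pan_cancer_meta(p_tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Combine per-cohort DE tables over a shared gene universe.

    Raw p-values are combined with Fisher's method (zeros clamped), BH
    re-adjusted, and fold changes summarized by their geometric mean.
    """
    if not p_tables:
        raise ValueError("need at least one DE table")
    index = p_tables[0].index
    for t in p_tables[1:]:
        if not t.index.equals(index):
            raise ValueError("DE tables must share one gene universe")
    p = np.column_stack([t["p"].to_numpy() for t in p_tables])
    fc = np.column_stack([t["fc"].to_numpy() for t in p_tables])
    combined = _fisher_meta_rows(p)
    return pd.DataFrame({
        "p": combined,
        "bh": bh_adjust(combined),
        "fc": np.exp(np.log(fc).mean(axis=1)),
    }, index=index)
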