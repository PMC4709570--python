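"""Independent brute-force oracles used by the test suite.

Each function re-derives a statistic from first principles (enumeration,
closed-form combinatorics, or an explicit walk) without touching the
implementation under test.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def bh_stepup(p):
    """Textbook Benjamini-Hochberg step-up adjustment."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adjusted = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(adjusted[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty_like(adjusted)
    out[order] = adjusted
    return out


def wilcoxon_exact_by_enumeration(x, y):
    """Two-sided exact rank-sum p by enumerating every group assignment.

    Assumes no ties. Two-sidedness is twice the smaller tail, capped at 1.
    """
    pooled = np.concatenate([x, y])
    ranks = np.argsort(np.argsort(pooled)) + 1
    n1 = len(x)
    w_obs = ranks[:n1].sum()
    sums = [sum(combo) for combo in
            itertools.combinations(ranks.tolist(), n1)]
    total = len(sums)
    cdf = sum(s <= w_obs for s in sums)
    sf = sum(s >= w_obs for s in sums)
    return min(1.0, 2.0 * min(cdf, sf) / total)


def hypergeom_tail(overlap, n_universe, n_pathway, n_draws):
    """P(X >= overlap) by exact integer combinatorics."""
    total = math.comb(n_universe, n_draws)
    upper = min(n_pathway, n_draws)
    acc = 0
    for k in range(overlap, upper + 1):
        acc += math.comb(n_pathway, k) * math.comb(n_universe - n_pathway,
                                                   n_draws - k)
    return acc / total


def ks_enrichment_walk(rank_of_query, n_genes):
    """Enrichment score by walking every position of the ranking."""
    hits = set(int(r) for r in rank_of_query)
    n = len(hits)
    step_hit = 1.0 / n
    step_miss = 1.0 / (n_genes - n)
    running = 0.0
    best = 0.0
    for position in range(1, n_genes + 1):
        running += step_hit if position in hits else -step_miss
        if abs(running) > abs(best) or (abs(running) == abs(best)
                                        and running > best):
            best = running
    return best
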