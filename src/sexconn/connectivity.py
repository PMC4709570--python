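"""In-repo connectivity-map scorer.

A perturbagen reference library stores, per perturbagen replicate, a
complete ranking of a fixed gene universe (rank 1 = most up-regulated by
the perturbagen). A query is a pair of disjoint gene sets: genes to
up-regulate and genes to down-regulate. Scoring follows the classic
connectivity-map lineage:

1. each set's enrichment in a profile is the signed maximum deviation of a
   Kolmogorov-Smirnov hit/miss running sum down the ranking;
2. the combined raw score is (ES_up - ES_down) / 2 when the two component
   enrichments disagree in sign and 0 otherwise;
3. raw scores are averaged over replicates and mapped to a signed
   percentile in [-100, 100]: the perturbagen with the strongest positive
   mean raw score in the library scores 100, the strongest negative -100.

The percentile normalization makes scores comparable across queries and
library sizes; it is exactly antisymmetric under exchange of the up and
down query sets.
"""

from __future__ import annotations

import logging
import os
from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import io

logger = logging.getLogger(__name__)

MANIFEST_COLUMNS = ("perturbagen", "replicate", "reagent_class", "planted_type")


class PerturbagenLibrary:
    """Ranked gene profiles per perturbagen replicate over a gene universe.

    Parameters
    ----------
    universe
        Ordered gene ids.
    ranks
        Gene x profile DataFrame; each column is a permutation of
        ``1..len(universe)`` with rank 1 the most up-regulated gene.
    manifest
        DataFrame indexed by profile id with columns ``perturbagen``,
        ``replicate``, ``reagent_class`` and ``planted_type`` (simulation
        ground truth, "null"/"I"/"II"/"III" or "" for real libraries).
    """

    def __init__(self, universe: Sequence[str], ranks: pd.DataFrame,
                 manifest: pd.DataFrame) -> None:
        universe = list(universe)
        if list(ranks.index) != universe:
            raise ValueError("rank matrix rows must equal the universe")
        if not ranks.columns.equals(pd.Index(manifest.index)):
            raise ValueError("manifest must be indexed by the profile columns")
        values = ranks.to_numpy()
        expected = np.arange(1, len(universe) + 1)
        if not np.array_equal(np.sort(values, axis=0),
                              expected[:, None].repeat(values.shape[1], axis=1)):
            raise ValueError("each profile must be a complete ranking "
                             "(a permutation of 1..n_genes)")
        for col in MANIFEST_COLUMNS[:3]:
            if col not in manifest:
                raise ValueError(f"manifest lacks required column {col!r}")
        self.universe = universe
        self.ranks = ranks.astype(int)
        self.manifest = manifest.copy()
        if "planted_type" not in self.manifest:
            self.manifest["planted_type"] = ""
        self._gene_pos = pd.Series(range(len(universe)), index=universe)
        self._rank_array = self.ranks.to_numpy().T  # profiles x genes

    @property
    def n_genes(self) -> int:
        return len(self.universe)

    @property
    def perturbagens(self) -> list[str]:
        return list(pd.unique(self.manifest["perturbagen"]))

    def query_indices(self, genes: Sequence[str], label: str = "query") -> np.ndarray:
        genes = list(genes)
        if not genes:
            raise ValueError(f"{label} gene set is empty")
        missing = [g for g in genes if g not in self._gene_pos.index]
        if missing:
            raise ValueError(f"{label} genes absent from universe: {missing}")
        return self._gene_pos.loc[genes].to_numpy()

    def write(self, gct_path: str | os.PathLike,
              manifest_path: str | os.PathLike) -> None:
        io.write_gct(self.ranks, gct_path,
                     descriptions=pd.Series(self.universe, index=self.universe))
        io.write_tsv(self.manifest, manifest_path, float_format=None)

    @classmethod
    def read(cls, gct_path: str | os.PathLike,
             manifest_path: str | os.PathLike) -> "PerturbagenLibrary":
        ranks, _ = io.read_gct(gct_path)
        # keep_default_na: "null" is a meaningful planted-type label here
        manifest = pd.read_csv(manifest_path, sep="\t", index_col=0,
                               keep_default_na=False)
        if "planted_type" not in manifest:
            manifest["planted_type"] = ""
        return cls(list(ranks.index), ranks, manifest)


# ---------------------------------------------------------------------------
# Enrichment statistics
# ---------------------------------------------------------------------------

def _es_matrix(rank_array: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Unweighted KS enrichment score of one gene set in many profiles.

    ``rank_array`` is profiles x genes (values are ranks); ``idx`` indexes
    the query genes. For hit positions p_1 < ... < p_n in a universe of N
    genes the running sum after hit j is j/n - (p_j - j)/(N - n) and just
    before it is (j-1)/n - (p_j - j)/(N - n); the signed extremum over both
    families is the enrichment score.
    """
    n_profiles, n_genes = rank_array.shape
    n = idx.size
    if n == n_genes:
        logger.warning("query equals the entire universe; ES set to 0")
        return np.zeros(n_profiles)
    hits = np.sort(rank_array[:, idx], axis=1).astype(float)
    j = np.arange(1, n + 1, dtype=float)
    miss_frac = (hits - j) / (n_genes - n)
    dev_after = j / n - miss_frac
    dev_before = (j - 1.0) / n - miss_frac
    mx = dev_after.max(axis=1)
    mn = dev_before.min(axis=1)
    return np.where(mx >= -mn, mx, mn)


def _profile_to_rank_row(profile, universe: Sequence[str] | None) -> tuple[np.ndarray, list[str]]:
    if isinstance(profile, pd.Series):
        return profile.to_numpy(dtype=int)[None, :], list(profile.index)
    if universe is None:
        raise ValueError("a universe is required with a bare rank array")
    return np.asarray(profile, dtype=int)[None, :], list(universe)


def enrichment_score(query_set: Sequence[str], profile,
                     universe: Sequence[str] | None = None) -> float:
    """Signed KS enrichment of ``query_set`` in one ranked profile.

    ``profile`` is a pandas Series mapping gene id -> rank (or a bare rank
    array with an explicit ``universe``). ES is in [-1, 1]; positive means
    the set concentrates near the top (most up-regulated) of the profile.
    """
    row, genes = _profile_to_rank_row(profile, universe)
    pos = pd.Series(range(len(genes)), index=genes)
    query = list(query_set)
    if not query:
        raise ValueError("query gene set is empty")
    missing = [g for g in query if g not in pos.index]
    if missing:
        raise ValueError(f"query genes absent from universe: {missing}")
    return float(_es_matrix(row, pos.loc[query].to_numpy())[0])


def _wtcs_matrix(rank_array: np.ndarray, up_idx: np.ndarray,
                 down_idx: np.ndarray) -> np.ndarray:
    es_up = _es_matrix(rank_array, up_idx)
    es_down = _es_matrix(rank_array, down_idx)
    opposite = es_up * es_down < 0
    return np.where(opposite, (es_up - es_down) / 2.0, 0.0)


def wtcs(up_set: Sequence[str], down_set: Sequence[str], profile,
         universe: Sequence[str] | None = None) -> float:
    """Two-sided connectivity score of an up/down query in one profile.

    Equal to (ES(up) - ES(down)) / 2 when the two enrichments disagree in
    sign and 0 otherwise, hence in [-1, 1] and antisymmetric under
    exchanging the up and down sets.
    """
    if set(up_set) & set(down_set):
        raise ValueError("up and down sets must be disjoint")
    es_up = enrichment_score(up_set, profile, universe)
    es_down = enrichment_score(down_set, profile, universe)
    if es_up * es_down < 0:
        return (es_up - es_down) / 2.0
    return 0.0


# ---------------------------------------------------------------------------
# Replicate aggregation and normalization
# ---------------------------------------------------------------------------

def normalize_and_aggregate(raw_scores: pd.Series,
                            manifest: pd.DataFrame) -> pd.DataFrame:
    """Per-profile raw scores -> per-perturbagen normalized scores.

    Raw scores are averaged over a perturbagen's replicates; the normalized
    score is sign(mean) * 100 * rank-percentile of |mean| within the
    same-sign perturbagens (average ranks on ties), so the strongest
    positive connection in the library scores 100 and the strongest
    negative -100; zero means no (or sign-conflicted) connection.
    """
    pert = manifest.loc[raw_scores.index, "perturbagen"]
    mean_raw = raw_scores.groupby(pert, sort=False).mean()
    order = pd.unique(pert)
    mean_raw = mean_raw.loc[order]
    n_reps = raw_scores.groupby(pert, sort=False).size().loc[order]
    values = mean_raw.to_numpy()
    score = np.zeros_like(values)
    pos = values > 0
    neg = values < 0
    if pos.sum() == 0 or neg.sum() == 0:
        logger.warning("degenerate sign class (n+=%d, n-=%d); percentile "
                       "normalization is coarse", int(pos.sum()), int(neg.sum()))
    if pos.any():
        score[pos] = 100.0 * rankdata(values[pos], method="average") / pos.sum()
    if neg.any():
        score[neg] = -100.0 * rankdata(-values[neg], method="average") / neg.sum()
    return pd.DataFrame({"mean_raw": values, "score": score,
                         "n_replicates": n_reps.to_numpy()},
                        index=pd.Index(order, name="perturbagen"))


def score_library(library: PerturbagenLibrary, up_set: Sequence[str],
                  down_set: Sequence[str]) -> pd.DataFrame:
    """Score every perturbagen of a library against one up/down query."""
    if set(up_set) & set(down_set):
        raise ValueError("up and down sets must be disjoint")
    up_idx = library.query_indices(up_set, "up")
    down_idx = library.query_indices(down_set, "down")
    raw = pd.Series(_wtcs_matrix(library._rank_array, up_idx, down_idx),
                    index=library.ranks.columns)
    result = normalize_and_aggregate(raw, library.manifest)
    classes = library.manifest.drop_duplicates("perturbagen").set_index(
        "perturbagen")["reagent_class"]
    result["reagent_class"] = classes.loc[result.index].to_numpy()
    return result
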