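"""Permutation-calibrated differential connectivity and Type I/II/III calls.

The male-female difference in a perturbagen's connectivity score is
calibrated against a null built by permuting sample sex labels (sex counts
held fixed, tissue labels untouched): each permutation re-derives the
sex-stratified tumor-vs-normal signatures and re-scores the whole library,
yielding one null difference per perturbagen per permutation. The
empirical p-value of a perturbagen is the fraction of permutations whose
difference magnitude meets or exceeds the observed one; Benjamini-Hochberg
adjustment across perturbagens gives BH values.

Perturbagen classes:

* Type I — sex-differential (BH below ``alpha_sexspec``) with a positive
  male and negative female score: predicted male-sensitive/female-resistant;
* Type II — the mirror image: female-sensitive/male-resistant;
* Type III — no significant sex difference (BH above ``bh_floor_type3``)
  with scores of at least ``score_floor_type3`` in both sexes: predicted
  sensitive in both.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import diffexp
from .connectivity import PerturbagenLibrary, score_library
from .dataset import ExpressionDataset
from .signatures import DEFAULT_SIZE_CAP, SignaturePair, build_signatures

logger = logging.getLogger(__name__)

TYPES = ("I", "II", "III", "none")


@dataclass(frozen=True)
class Thresholds:
    """All tunable decision constants of the permutation pipeline.

    ``bh_floor_type3`` defaults to ``alpha_sexspec``: a Type III call
    requires the sex difference to be non-significant (BH above the floor)
    on top of the score floor in both sexes.
    """

    alpha_sexspec: float = 0.05
    bh_floor_type3: float = 0.05
    score_floor_type3: float = 90.0
    n_permutations: int = 1000
    alpha_de: float = 0.05
    signature_cap: int = DEFAULT_SIZE_CAP
    min_per_arm: int = 10
    pseudocount: float = 1.0
    add_one: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha_sexspec < 1.0:
            raise ValueError("alpha_sexspec must lie in (0, 1)")
        if not self.alpha_sexspec <= self.bh_floor_type3 < 1.0:
            raise ValueError("bh_floor_type3 must lie in [alpha_sexspec, 1)")
        if not 0.0 < self.score_floor_type3 <= 100.0:
            raise ValueError("score_floor_type3 must lie in (0, 100]")
        if self.n_permutations < 0:
            raise ValueError("n_permutations must be nonnegative")


def permute_sex_labels(dataset: ExpressionDataset,
                       rng: np.random.Generator | int) -> ExpressionDataset:
    """Uniformly permute sex labels across samples; counts are preserved."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    sexes = set(dataset.sample_sex)
    if len(sexes) < 2:
        raise ValueError("dataset contains a single sex")
    permuted = rng.permutation(dataset.sample_sex.to_numpy())
    return dataset.with_sample_sex(permuted)


def empirical_p(obs_diff: float, null_diffs, add_one: bool = False) -> float:
    """Two-sided (on magnitude) empirical p-value against a permutation null.

    p = #{|null| >= |obs|} / N by default; an exact zero is attainable and
    is passed downstream as-is. ``add_one`` switches to the (r+1)/(N+1)
    variant that cannot reach zero.
    """
    null_diffs = np.asarray(null_diffs, dtype=float)
    if null_diffs.size == 0:
        raise ValueError("null distribution is empty")
    r = int((np.abs(null_diffs) >= abs(obs_diff)).sum())
    n = null_diffs.size
    return (r + 1) / (n + 1) if add_one else r / n


def classify_perturbagen(male_score: float, female_score: float, bh: float,
                         thresholds: Thresholds = Thresholds()) -> str:
    """Type call from the two sex scores and the permutation BH value.

    Boundary BH values (exactly at a threshold) fall to "none"; a
    sex-significant perturbagen whose scores agree in sign is also "none".
    """
    for score in (male_score, female_score):
        if not -100.0 <= score <= 100.0:
            raise ValueError("scores must lie in [-100, 100]")
    if not 0.0 <= bh <= 1.0:
        raise ValueError("bh must lie in [0, 1]")
    if bh < thresholds.alpha_sexspec:
        if male_score > 0 and female_score < 0:
            return "I"
        if male_score < 0 and female_score > 0:
            return "II"
        return "none"
    if (bh > thresholds.bh_floor_type3
            and male_score >= thresholds.score_floor_type3
            and female_score >= thresholds.score_floor_type3):
        return "III"
    return "none"


def tally_types(types) -> dict[str, int]:
    """Per-cohort counts of each type; sex-specific = Type I + Type II."""
    counts = pd.Series(list(types)).value_counts()
    out = {t: int(counts.get(t, 0)) for t in TYPES}
    out["total_sex_specific"] = out["I"] + out["II"]
    return out


# ---------------------------------------------------------------------------
# Signature scoring under one labeling
# ---------------------------------------------------------------------------

def _signature_for_labels(values: np.ndarray, sex: np.ndarray,
                          tissue: np.ndarray, gene_index: pd.Index,
                          which_sex: str, thresholds: Thresholds,
                          cancer_label: str = "") -> SignaturePair | None:
    """DE + signature construction for one sex under given labels.

    Returns None when an arm is too small to test (fewer than two samples)
    or the resulting signature pair is empty.
    """
    tumor = (sex == which_sex) & (tissue == "tumor")
    normal = (sex == which_sex) & (tissue == "normal")
    if tumor.sum() < 2 or normal.sum() < 2:
        return None
    de = diffexp._de_table(values[:, tumor], values[:, normal], gene_index,
                           thresholds.alpha_de, thresholds.pseudocount)
    pair = build_signatures(de, which_sex, cancer_label,
                            size_cap=thresholds.signature_cap,
                            alpha=thresholds.alpha_de)
    return None if pair.is_empty else pair


def _scores_for_labels(values: np.ndarray, sex: np.ndarray,
                       tissue: np.ndarray, gene_index: pd.Index,
                       library: PerturbagenLibrary, thresholds: Thresholds,
                       cancer_label: str = "") -> pd.DataFrame | None:
    """Per-perturbagen male/female scores under one sex labeling.

    Returns both the normalized scores (reporting and classification
    scale) and the raw replicate-mean connectivity scores: the permutation
    null compares male-female differences on the raw scale, which carries
    magnitude, whereas the percentile scale is relative to the rest of the
    library and saturates.
    """
    scores = {}
    for which_sex in ("male", "female"):
        pair = _signature_for_labels(values, sex, tissue, gene_index,
                                     which_sex, thresholds, cancer_label)
        if pair is None:
            return None
        pair, _ = pair.restrict_to(library.universe)
        if pair.is_empty:
            return None
        scores[which_sex] = score_library(
            library, up_set=pair.sensitivity, down_set=pair.resistance)
    return pd.DataFrame({"male_score": scores["male"]["score"],
                         "female_score": scores["female"]["score"],
                         "male_raw": scores["male"]["mean_raw"],
                         "female_raw": scores["female"]["mean_raw"]})


@dataclass
class DifferentialConnectivity:
    """Observed scores, permutation null, and type calls for one cohort."""

    table: pd.DataFrame        # per perturbagen: scores, diff, p, bh, type
    null_diffs: np.ndarray     # perturbagens x permutations
    thresholds: Thresholds
    cancer_label: str = ""

    def tally(self) -> dict[str, int]:
        return tally_types(self.table["type"])


def null_distribution(dataset: ExpressionDataset, library: PerturbagenLibrary,
                      thresholds: Thresholds,
                      rng: np.random.Generator | None = None) -> np.ndarray:
    """Male-female raw connectivity differences under sex-label permutations.

    Returns a perturbagens x N matrix of differences of replicate-mean raw
    connectivity scores. Permutations in which either sex's signature comes
    up empty (or an arm degenerates) contribute a zero difference for every
    perturbagen, with a logged warning.
    """
    if thresholds.n_permutations == 0:
        raise ValueError("n_permutations must be positive to build a null")
    if rng is None:
        rng = np.random.default_rng(thresholds.seed)
    values = dataset.matrix.to_numpy()
    tissue = dataset.sample_tissue.to_numpy()
    base_sex = dataset.sample_sex.to_numpy()
    gene_index = dataset.matrix.index
    n_pert = len(library.perturbagens)
    nulls = np.zeros((n_pert, thresholds.n_permutations))
    n_degenerate = 0
    for k in range(thresholds.n_permutations):
        perm_sex = rng.permutation(base_sex)
        scores = _scores_for_labels(values, perm_sex, tissue, gene_index,
                                    library, thresholds,
                                    dataset.cancer_label)
        if scores is None:
            n_degenerate += 1
            continue  # column stays zero
        nulls[:, k] = (scores["male_raw"] - scores["female_raw"]).to_numpy()
    if n_degenerate:
        logger.warning("%d of %d permutations yielded an empty signature; "
                       "their differences were recorded as 0",
                       n_degenerate, thresholds.n_permutations)
    return nulls


def differential_connectivity(dataset: ExpressionDataset,
                              library: PerturbagenLibrary,
                              thresholds: Thresholds = Thresholds(),
                              ) -> DifferentialConnectivity:
    """Full observed + permutation analysis of one cohort against a library."""
    values = dataset.matrix.to_numpy()
    tissue = dataset.sample_tissue.to_numpy()
    sex = dataset.sample_sex.to_numpy()
    for which_sex in ("male", "female"):
        for arm, label in (("tumor", "tumor"), ("normal", "normal")):
            n = int(((sex == which_sex) & (tissue == label)).sum())
            if n < thresholds.min_per_arm:
                raise ValueError(
                    f"{which_sex} {arm} arm has {n} samples, below the "
                    f"floor of {thresholds.min_per_arm}")
    observed = _scores_for_labels(values, sex, tissue, dataset.matrix.index,
                                  library, thresholds, dataset.cancer_label)
    if observed is None:
        raise ValueError("observed signatures are empty; nothing to query")
    obs_diff = (observed["male_raw"] - observed["female_raw"]).to_numpy()

    rng = np.random.default_rng(thresholds.seed)
    nulls = null_distribution(dataset, library, thresholds, rng)
    p = np.array([empirical_p(obs_diff[i], nulls[i], thresholds.add_one)
                  for i in range(len(obs_diff))])
    bh = diffexp.bh_adjust(p)
    types = [classify_perturbagen(m, f, b, thresholds)
             for m, f, b in zip(observed["male_score"],
                                observed["female_score"], bh)]
    table = observed.copy()
    table["obs_diff"] = obs_diff
    table["p"] = p
    table["bh"] = bh
    table["type"] = types
    planted = library.manifest.drop_duplicates("perturbagen").set_index(
        "perturbagen")["planted_type"]
    table["planted_type"] = planted.reindex(table.index).fillna("").to_numpy()
    return DifferentialConnectivity(table, nulls, thresholds,
                                    dataset.cancer_label)
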