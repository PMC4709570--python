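"""Multivariate sex classification from expression.

An L1-regularized (LASSO) logistic regression is fit to classify sample
sex from expression; features are standardized so the penalty is
comparable across genes of different scale. The penalty is chosen on a
small grid by the one-standard-error rule on cross-validated
misclassification error (the sparsest model statistically tied with the
best), accuracy is the area under the ROC curve of held-out predictions
pooled over 10 stratified folds, and the reported "active transcripts"
are the genes with nonzero coefficients in a final all-sample fit at the
selected penalty.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .dataset import ExpressionDataset

DEFAULT_C_GRID = tuple(np.logspace(-3, 2, 11))


@dataclass
class SexClassifierResult:
    """Cross-validated LASSO sex classifier summary."""

    active: pd.DataFrame          # gene, coefficient (nonzero only)
    cv_auc: float
    c: float                      # inverse penalty strength selected by CV
    fold_assignments: pd.Series   # sample id -> fold index
    universe: list[str]
    cancer_label: str = ""

    @property
    def lambda_(self) -> float:
        return 1.0 / self.c

    @property
    def n_active(self) -> int:
        return len(self.active)

    @property
    def active_genes(self) -> list[str]:
        return list(self.active["gene"])


def _l1_pipeline(c: float) -> Pipeline:
    return Pipeline([
        ("scale", StandardScaler()),
        ("lasso", LogisticRegression(l1_ratio=1.0, solver="liblinear", C=c,
                                     max_iter=5000, random_state=0)),
    ])


def fit_sex_classifier(dataset: ExpressionDataset, n_folds: int = 10,
                       seed: int = 0,
                       c_grid: tuple[float, ...] = DEFAULT_C_GRID,
                       ) -> SexClassifierResult:
    """Fit the LASSO sex classifier with stratified cross-validation.

    The held-out AUC pools the out-of-fold predicted probabilities across
    all folds, so no sample is ever scored by a model that saw it during
    training. The penalty is chosen by the one-standard-error rule on
    cross-validated misclassification error, favoring the sparser
    (smaller C) model.
    Subset the dataset (e.g. to tumors) before calling when a
    tissue-restricted model is wanted.
    """
    y = (dataset.sample_sex == "female").to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("dataset contains a single sex")
    if min((y == 0).sum(), (y == 1).sum()) < n_folds:
        raise ValueError(f"need at least {n_folds} samples of each sex "
                         f"for {n_folds}-fold stratified CV")
    x = dataset.matrix.to_numpy().T
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(x, y))
    fold_of = np.empty(len(y), dtype=int)
    for k, (_, test) in enumerate(folds):
        fold_of[test] = k

    oof = {c: np.empty(len(y)) for c in c_grid}
    fold_err = {c: np.empty(len(folds)) for c in c_grid}
    for k, (train, test) in enumerate(folds):
        for c in c_grid:
            pipe = _l1_pipeline(c)
            pipe.fit(x[train], y[train])
            oof[c][test] = pipe.predict_proba(x[test])[:, 1]
            fold_err[c][k] = np.mean((oof[c][test] > 0.5) != y[test])
    # one-standard-error rule on CV misclassification error: the sparsest
    # (smallest C) model within one fold-to-fold SE of the minimum
    mean_err = {c: fold_err[c].mean() for c in c_grid}
    c_min = min(sorted(c_grid), key=lambda c: mean_err[c])
    se_min = fold_err[c_min].std(ddof=1) / np.sqrt(len(folds))
    best_c = next(c for c in sorted(c_grid)
                  if mean_err[c] <= mean_err[c_min] + se_min)
    cv_auc = float(roc_auc_score(y, oof[best_c]))

    final = _l1_pipeline(best_c).fit(x, y)
    coef = final.named_steps["lasso"].coef_.ravel()
    nz = np.flatnonzero(coef)
    active = pd.DataFrame({"gene": np.array(dataset.gene_ids)[nz],
                           "coefficient": coef[nz]})
    active = active.reindex(active["coefficient"].abs()
                            .sort_values(ascending=False).index
                            ).reset_index(drop=True)
    return SexClassifierResult(
        active=active, cv_auc=cv_auc, c=float(best_c),
        fold_assignments=pd.Series(fold_of, index=dataset.matrix.columns,
                                   name="fold"),
        universe=dataset.gene_ids, cancer_label=dataset.cancer_label)


def compare_tumor_normal_selection(result_tumor: SexClassifierResult,
                                   result_normal: SexClassifierResult,
                                   ) -> tuple[pd.DataFrame, list[str]]:
    """Which active transcripts differ between tumor and normal models.

    Returns a per-gene table of selection flags over the union of the two
    active sets, plus the discordant genes (selected in exactly one model).
    """
    if result_tumor.universe != result_normal.universe:
        raise ValueError("classifier results must share one gene universe")
    in_tumor = set(result_tumor.active_genes)
    in_normal = set(result_normal.active_genes)
    union = sorted(in_tumor | in_normal)
    table = pd.DataFrame({
        "selected_in_tumor": [g in in_tumor for g in union],
        "selected_in_normal": [g in in_normal for g in union],
    }, index=pd.Index(union, name="gene"))
    discordant = sorted(in_tumor ^ in_normal)
    return table, discordant
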