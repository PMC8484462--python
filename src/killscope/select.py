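"""Univariate feature ranking, correlation pruning, and top-k selection.

Each feature is scored on its own by cross-validated AUC under each of the
four classifier families; features are ranked per family and a consensus
order (mean rank across families) is formed.  Highly redundant features are
then pruned by a greedy top-down scan of the consensus order: a feature is
dropped when its absolute Pearson correlation with any already-retained,
higher-ranked feature exceeds the threshold (default 0.95).  The first k
survivors (default 10) form the model-input feature set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .classify import FAMILIES, ClassifierSpec, _binary_labels, make_estimator, roc_auc
from .imagefeat import FEATURE_NAMES

logger = logging.getLogger(__name__)


def _canonical_key(name: str) -> tuple:
    """Permutation-stable tie-break: canonical feature order, then name."""
    base = name.split("@")[0]
    if base in FEATURE_NAMES:
        return (0, FEATURE_NAMES.index(base), name)
    return (1, 0, name)


@dataclass
class FeatureRanking:
    """Per-model univariate AUCs and the consensus feature order.

    ``auc_table``: DataFrame features x families of oriented AUCs (in
    [0.5, 1]: a feature whose raw AUC falls below 0.5 separates the classes
    with the opposite threshold direction, so it is flipped to 1 - AUC).
    ``per_model``: per family, (feature, AUC) sorted by descending AUC.
    ``consensus``: features sorted by mean rank across families.
    """

    auc_table: pd.DataFrame
    per_model: dict[str, list[tuple[str, float]]]
    consensus: list[str]
    retained: list[str] | None = None


def univariate_rank(
    table: pd.DataFrame,
    labels,
    models: tuple[str, ...] = FAMILIES,
    n_folds: int = 5,
    seed: int = 0,
) -> FeatureRanking:
    """Rank every column of ``table`` by single-feature classification AUC.

    AUC is estimated by stratified k-fold cross-validation (out-of-fold
    scores, folds averaged) for each family.  Constant features get AUC 0.5
    without fitting.  Ties in the per-model and consensus orders are broken
    by the canonical feature order (then by name), so the ranking does not
    depend on the table's column order.
    """
    y = _binary_labels(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    counts = np.bincount(y)
    folds = min(n_folds, counts.min())
    if folds < 2:
        raise ValueError("need at least 2 samples per class")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(np.zeros(len(y)), y))

    features = list(table.columns)
    aucs = pd.DataFrame(index=features, columns=list(models), dtype=float)
    for feat in features:
        x = table[feat].to_numpy(dtype=float).reshape(-1, 1)
        if np.ptp(x) == 0:
            aucs.loc[feat] = 0.5
            continue
        for fam in models:
            fold_aucs = []
            for tr, te in splits:
                est = make_estimator(ClassifierSpec(family=fam, seed=seed))
                est.fit(x[tr], y[tr])
                if fam == "SVM":
                    s = est.decision_function(x[te])
                else:
                    s = est.predict_proba(x[te])[:, 1]
                if len(np.unique(y[te])) < 2:
                    continue
                _, a = roc_auc(s, y[te])
                fold_aucs.append(a)
            a = float(np.mean(fold_aucs))
            aucs.loc[feat, fam] = max(a, 1.0 - a)

    per_model = {}
    ranks = pd.DataFrame(index=features, columns=list(models), dtype=float)
    for fam in models:
        ordered = sorted(features, key=lambda f: (-aucs.loc[f, fam], _canonical_key(f)))
        per_model[fam] = [(f, float(aucs.loc[f, fam])) for f in ordered]
        for r, f in enumerate(ordered):
            ranks.loc[f, fam] = r
    mean_rank = ranks.mean(axis=1)
    consensus = sorted(features, key=lambda f: (mean_rank[f], _canonical_key(f)))
    return FeatureRanking(auc_table=aucs, per_model=per_model, consensus=consensus)


def correlation_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation between features over samples.

    Exactly symmetric with a unit diagonal; zero-variance features get 0
    off-diagonal (logged) rather than NaN.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 samples")
    corr = table.corr(method="pearson")
    if corr.isna().any().any():
        degenerate = [c for c in table.columns if table[c].nunique() <= 1]
        if degenerate:
            logger.info("zero-variance features set to 0 correlation: %s", degenerate)
        corr = corr.fillna(0.0)
    vals = (corr.to_numpy() + corr.to_numpy().T) / 2.0
    np.fill_diagonal(vals, 1.0)
    return pd.DataFrame(vals, index=corr.index, columns=corr.columns)


def prune(
    ranking: FeatureRanking,
    corr: pd.DataFrame,
    threshold: float = 0.95,
    k: int = 10,
) -> list[str]:
    """Greedy redundancy pruning of the consensus order; keep the top k.

    Scanning from the best-ranked feature down, a feature is dropped when
    its |Pearson r| with any already-retained feature is strictly above the
    threshold; the scan stops after k survivors.  If fewer than k survive,
    all survivors are returned with a warning.
    """
    retained: list[str] = []
    for feat in ranking.consensus:
        if feat not in corr.index:
            continue
        if any(abs(float(corr.loc[feat, r])) > threshold for r in retained):
            continue
        retained.append(feat)
        if len(retained) == k:
            break
    if len(retained) < k:
        logger.warning("only %d of %d requested features survive pruning", len(retained), k)
    ranking.retained = retained
    return retained
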