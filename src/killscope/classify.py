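"""Classifier families, ROC/AUC, balanced splits, and the combinatorial sweep.

Four standard families are compared: Gaussian naive Bayes, L2 logistic
regression, an RBF support-vector machine, and a random forest.  Each is
trained on every non-empty subset of the k selected features (2^k - 1
combinations, 1023 for k = 10) for each input format, and scored by the
area under the ROC curve on the training split and on several set-aside
validation splits.  Splits are balanced per class and made at the track
level so that no window of a training track can leak into validation.

``roc_auc`` is implemented as an explicit threshold sweep with trapezoidal
integration; it equals the pairwise-concordance (rank-sum) statistic, which
the test suite verifies against an O(n^2) oracle.
"""

from __future__ import annotations

import itertools
import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC

FAMILIES = ("Bayes", "LR", "SVM", "RF")

#: label convention: "killed" is the positive class throughout.
POSITIVE_LABEL = "killed"


@dataclass(frozen=True)
class ClassifierSpec:
    """One model family with its fixed hyperparameters.

    Hyperparameters are deliberately plain toolbox settings: GaussianNB
    with defaults; logistic regression with unit inverse regularization;
    RBF SVM with the scale gamma heuristic (scored by decision function);
    random forest with 100 trees, unlimited depth and sqrt(#features) per
    split.  ``seed`` fixes all stochastic fits.
    """

    family: str
    seed: int = 0
    rf_n_estimators: int = 100
    lr_c: float = 1.0
    svm_c: float = 1.0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}")


class FittedModel:
    """A fitted classifier exposing a killed-probability-monotone score."""

    def __init__(self, spec: ClassifierSpec, estimator, feature_columns: list[str]):
        self.spec = spec
        self.estimator = estimator
        self.feature_columns = feature_columns

    @property
    def default_threshold(self) -> float:
        """Score above which a window is called "killed" (probability 0.5;
        decision-function 0 for the SVM)."""
        return 0.0 if self.spec.family == "SVM" else 0.5

    def scores(self, X) -> np.ndarray:
        X = _as_matrix(X, self.feature_columns)
        if self.spec.family == "SVM":
            return self.estimator.decision_function(X)
        return self.estimator.predict_proba(X)[:, 1]

    def save(self, path: str | Path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path: str | Path) -> "FittedModel":
        with open(path, "rb") as fh:
            return pickle.load(fh)


def _as_matrix(X, columns: list[str] | None = None) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        if columns is not None:
            X = X[columns]
        return X.to_numpy(dtype=float)
    return np.asarray(X, dtype=float)


def make_estimator(spec: ClassifierSpec):
    if spec.family == "Bayes":
        return GaussianNB()
    if spec.family == "LR":
        return LogisticRegression(C=spec.lr_c, max_iter=2000)
    if spec.family == "SVM":
        return SVC(C=spec.svm_c, kernel="rbf", gamma="scale")
    return RandomForestClassifier(
        n_estimators=spec.rf_n_estimators,
        max_features="sqrt",
        random_state=spec.seed,
        n_jobs=1,
    )


def train(spec: ClassifierSpec, X, y) -> FittedModel:
    """Fit one classifier; scores are monotone in predicted kill probability.

    ``y`` may be string labels ("killed"/"alive") or {0, 1}.  NaN in X is an
    error — invalid windows must be dropped upstream.
    """
    cols = list(X.columns) if isinstance(X, pd.DataFrame) else None
    Xm = _as_matrix(X, cols)
    if not np.all(np.isfinite(Xm)):
        raise ValueError("non-finite values in model input")
    yb = _binary_labels(y)
    est = make_estimator(spec)
    est.fit(Xm, yb)
    return FittedModel(spec, est, cols)


def _binary_labels(y) -> np.ndarray:
    arr = np.asarray(y)
    if arr.dtype.kind in "UOS":
        return (arr == POSITIVE_LABEL).astype(int)
    return arr.astype(int)


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

def roc_auc(scores, labels) -> tuple[np.ndarray, float]:
    """ROC curve and area by explicit threshold sweep.

    Thresholds are the unique score values from high to low; tied scores
    advance the curve diagonally, so the trapezoidal area equals the
    pairwise-concordance statistic with ties counted 1/2.  Returns
    ``(points, auc)`` where points is an (m, 2) array of (FPR, TPR)
    starting at (0, 0) and ending at (1, 1).
    """
    s = np.asarray(scores, dtype=float)
    y = _binary_labels(labels)
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute a ROC curve")

    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    # indices where the threshold changes (last occurrence of each unique score)
    distinct = np.nonzero(np.diff(s_sorted))[0]
    cut = np.concatenate([distinct, [len(s) - 1]])
    tp = np.cumsum(y_sorted)[cut]
    fp = np.cumsum(1 - y_sorted)[cut]
    tpr = np.concatenate([[0.0], tp / n_pos])
    fpr = np.concatenate([[0.0], fp / n_neg])
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


# ---------------------------------------------------------------------------
# Splits
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitPlan:
    """Balanced train/validation sampling plan (counts are per class)."""

    n_train_per_class: int = 200
    n_validation_sets: int = 3
    n_val_per_class: int = 67
    seed: int = 0


def make_splits(meta: pd.DataFrame, plan: SplitPlan) -> dict:
    """Sample balanced, track-disjoint train and validation window sets.

    ``meta`` needs columns ``window_id``, ``track_id`` and ``label`` in
    {"alive", "killed"}; one window per track is expected (the pipeline's
    dataset builders guarantee it).  Returns
    ``{"train": [window ids], "validation": [[ids], ...]}`` with exactly the
    planned per-class counts, all sets mutually disjoint.  Raises
    ``ValueError`` when the pools are too small.
    """
    rng = np.random.default_rng(plan.seed)
    need = plan.n_train_per_class + plan.n_validation_sets * plan.n_val_per_class
    picked: dict[str, list[np.ndarray]] = {}
    for cls in ("alive", "killed"):
        pool = meta[meta["label"] == cls]
        if pool["track_id"].duplicated().any():
            raise ValueError("expected one window per track in the split pool")
        if len(pool) < need:
            raise ValueError(
                f"not enough {cls} windows: need {need}, have {len(pool)}"
            )
        ids = pool["window_id"].to_numpy()
        rng.shuffle(ids)
        chunks = [ids[: plan.n_train_per_class]]
        off = plan.n_train_per_class
        for _ in range(plan.n_validation_sets):
            chunks.append(ids[off : off + plan.n_val_per_class])
            off += plan.n_val_per_class
        picked[cls] = chunks
    train_ids = np.concatenate([picked["alive"][0], picked["killed"][0]])
    vals = [
        np.concatenate([picked["alive"][1 + i], picked["killed"][1 + i]])
        for i in range(plan.n_validation_sets)
    ]
    return {"train": sorted(int(i) for i in train_ids),
            "validation": [sorted(int(i) for i in v) for v in vals]}


# ---------------------------------------------------------------------------
# Sweep
# ---------------------------------------------------------------------------

@dataclass
class SweepResult:
    family: str
    input_type: str
    subset_mask: int
    feature_subset: list[str]
    train_auc: float
    val_aucs: list[float]
    roc: np.ndarray | None = None

    @property
    def mean_val_auc(self) -> float:
        return float(np.mean(self.val_aucs)) if self.val_aucs else float("nan")


def subset_columns(columns, features: list[str]) -> list[str]:
    """Columns of an input table belonging to the given base features."""
    keep = set(features)
    return [c for c in columns if c.split("@")[0] in keep]


def sweep(
    table: pd.DataFrame,
    labels: pd.Series,
    top_features: list[str],
    input_type: str,
    family: str,
    splits: dict,
    seed: int = 0,
    keep_roc: bool = False,
) -> list[SweepResult]:
    """Train one family on every non-empty subset of the top features.

    ``table`` is an input table (rows indexed by window_id) for
    ``input_type``; ``labels`` is aligned by window_id.  For each of the
    2^k - 1 subset bitmasks (bit i = include top_features[i]) the model is
    trained on the training split and scored on the training and every
    validation split.  Exactly ``2**k - 1`` results are returned.
    """
    k = len(top_features)
    if k < 1:
        raise ValueError("need at least one feature")
    spec = ClassifierSpec(family=family, seed=seed)
    train_idx = splits["train"]
    ytr = labels.loc[train_idx]
    results = []
    for mask in range(1, 2**k):
        feats = [top_features[i] for i in range(k) if mask >> i & 1]
        cols = subset_columns(table.columns, feats)
        model = train(spec, table.loc[train_idx, cols], ytr)
        roc_tr, auc_tr = roc_auc(model.scores(table.loc[train_idx, cols]), ytr)
        val_aucs = []
        for vidx in splits["validation"]:
            _, a = roc_auc(model.scores(table.loc[vidx, cols]), labels.loc[vidx])
            val_aucs.append(a)
        results.append(
            SweepResult(
                family=family,
                input_type=input_type,
                subset_mask=mask,
                feature_subset=feats,
                train_auc=auc_tr,
                val_aucs=val_aucs,
                roc=roc_tr if keep_roc else None,
            )
        )
    return results


def compare_inputs(results: list[SweepResult]) -> tuple[pd.DataFrame, SweepResult]:
    """Summarize sweep AUCs per (family, input type) and pick the top config.

    The top configuration maximizes training AUC; ties prefer fewer
    features, then the lowest subset bitmask.  Returns (summary, top) where
    summary has mean/sd/max train AUC and mean validation AUC per group.
    """
    if not results:
        raise ValueError("no sweep results")
    df = pd.DataFrame(
        {
            "family": [r.family for r in results],
            "input_type": [r.input_type for r in results],
            "train_auc": [r.train_auc for r in results],
            "mean_val_auc": [r.mean_val_auc for r in results],
        }
    )
    summary = (
        df.groupby(["family", "input_type"])
        .agg(
            mean_auc=("train_auc", "mean"),
            sd_auc=("train_auc", "std"),
            max_auc=("train_auc", "max"),
            mean_val_auc=("mean_val_auc", "mean"),
        )
        .reset_index()
    )
    top = min(
        results,
        key=lambda r: (-r.train_auc, len(r.feature_subset), r.subset_mask),
    )
    return summary, top


def sweep_to_frame(results: list[SweepResult]) -> pd.DataFrame:
    """Flatten sweep results for CSV export."""
    rows = []
    for r in results:
        row = {
            "family": r.family,
            "input_type": r.input_type,
            "subset_mask": r.subset_mask,
            "features": "|".join(r.feature_subset),
            "n_features": len(r.feature_subset),
            "train_auc": r.train_auc,
        }
        for i, a in enumerate(r.val_aucs, start=1):
            row[f"val_auc_{i}"] = a
        rows.append(row)
    return pd.DataFrame(rows)
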