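"""In silico dilution: rare killing events in large alive backgrounds.

To emulate a clinical sample in which tumor-reactive T cells — and hence
killing events — are rare, evaluation datasets are assembled by mixing a
fixed number of killed windows with progressively larger alive pools
(1:1, 1:10, ... 1:100,000), and a frozen, previously trained classifier is
scored on each without any retraining.  At each ratio, many datasets are
drawn independently so the spread of AUC across rare-event draws is
visible.

When the alive pool cannot supply ``base_killed_count * ratio`` cases, the
alive count is clipped to the pool and the killed count is reduced to
preserve the ratio (never below one killed event), which reproduces the
single-event datasets seen at extreme dilutions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import FittedModel, roc_auc

DEFAULT_RATIOS = (1, 10, 100, 1000, 10000, 100000)


@dataclass
class DilutionPlan:
    """Dataset-construction plan.

    ``ratios`` are alive-per-killed multipliers (1 -> 1:1, 10 -> 1:10 ...),
    strictly increasing.  ``killed_pool``/``alive_pool`` are input tables
    (rows = windows, columns = model-input features), disjoint from any
    training data.  Sampling is without replacement within a dataset and
    independent across the ``n_datasets_per_ratio`` datasets.
    """

    killed_pool: pd.DataFrame
    alive_pool: pd.DataFrame
    ratios: tuple[int, ...] = DEFAULT_RATIOS
    n_datasets_per_ratio: int = 30
    base_killed_count: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if list(self.ratios) != sorted(set(self.ratios)):
            raise ValueError("ratios must be strictly increasing")
        if len(self.killed_pool) == 0:
            raise ValueError("killed pool is empty")
        if len(self.alive_pool) == 0:
            raise ValueError("alive pool is empty")


@dataclass
class DilutionDataset:
    ratio: int
    dataset_index: int
    X: pd.DataFrame
    y: np.ndarray  # 1 = killed

    @property
    def n_killed(self) -> int:
        return int(self.y.sum())

    @property
    def n_alive(self) -> int:
        return int(len(self.y) - self.y.sum())


def planned_counts(plan: DilutionPlan, ratio: int) -> tuple[int, int]:
    """(n_killed, n_alive) for one dataset at the given ratio.

    Target: ``base_killed_count`` killed and ``base_killed_count * ratio``
    alive; both clipped to pool sizes, with the killed count reduced first
    (``max(1, floor(n_alive / ratio))``) when the alive supply binds.
    """
    n_alive = min(len(plan.alive_pool), plan.base_killed_count * ratio)
    if n_alive < plan.base_killed_count * ratio:
        n_killed = max(1, n_alive // ratio)
    else:
        n_killed = plan.base_killed_count
    n_killed = min(n_killed, len(plan.killed_pool))
    return int(n_killed), int(n_alive)


def build_datasets(plan: DilutionPlan) -> list[DilutionDataset]:
    """Draw every dataset of the plan; exactly reproducible from the seed."""
    datasets = []
    for ri, ratio in enumerate(plan.ratios):
        n_killed, n_alive = planned_counts(plan, ratio)
        for d in range(plan.n_datasets_per_ratio):
            rng = np.random.default_rng([plan.seed, ri, d])
            ki = rng.choice(len(plan.killed_pool), size=n_killed, replace=False)
            ai = rng.choice(len(plan.alive_pool), size=n_alive, replace=False)
            X = pd.concat(
                [plan.killed_pool.iloc[ki], plan.alive_pool.iloc[ai]], ignore_index=True
            )
            y = np.concatenate([np.ones(n_killed, dtype=int), np.zeros(n_alive, dtype=int)])
            datasets.append(DilutionDataset(ratio=ratio, dataset_index=d, X=X, y=y))
    return datasets


def evaluate(model: FittedModel, datasets: list[DilutionDataset]) -> pd.DataFrame:
    """Score every dataset with the frozen model; one AUC per dataset.

    No retraining and no threshold refitting — the model is applied exactly
    as trained.  Returns a table (ratio, dataset_index, n_killed, n_alive,
    auc).
    """
    rows = []
    for ds in datasets:
        _, auc = roc_auc(model.scores(ds.X), ds.y)
        rows.append(
            {
                "ratio": ds.ratio,
                "dataset_index": ds.dataset_index,
                "n_killed": ds.n_killed,
                "n_alive": ds.n_alive,
                "auc": auc,
            }
        )
    return pd.DataFrame(rows)


def summarize(results: pd.DataFrame) -> pd.DataFrame:
    """Median / mean / min AUC per ratio."""
    return (
        results.groupby("ratio")["auc"]
        .agg(["median", "mean", "min", "max"])
        .reset_index()
    )
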