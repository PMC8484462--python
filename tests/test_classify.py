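"""ROC/AUC statistic, classifier training, splits, and the subset sweep."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import roc_auc_score

from killscope.classify import (
    FAMILIES,
    ClassifierSpec,
    SplitPlan,
    SweepResult,
    compare_inputs,
    make_splits,
    roc_auc,
    subset_columns,
    sweep,
    train,
)


def concordance_auc(scores, labels):
    """O(n^2) oracle: fraction of (killed, alive) pairs ranked correctly,
    ties counted 1/2."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    pos, neg = s[y == 1], s[y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        _, a = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert a == 1.0

    def test_all_tied_scores_give_half(self):
        pts, a = roc_auc([0.5] * 10, [1, 0] * 5)
        assert a == 0.5
        np.testing.assert_array_equal(pts[0], [0, 0])
        np.testing.assert_array_equal(pts[-1], [1, 1])

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])

    def test_curve_monotone_and_anchored(self):
        rng = np.random.default_rng(0)
        labels = np.r_[1, 0, rng.integers(0, 2, 98)]
        pts, _ = roc_auc(rng.normal(size=100), labels)
        assert np.all(np.diff(pts[:, 0]) >= 0) and np.all(np.diff(pts[:, 1]) >= 0)
        np.testing.assert_array_equal(pts[0], [0.0, 0.0])
        np.testing.assert_array_equal(pts[-1], [1.0, 1.0])

    def test_matches_concordance_oracle_with_ties(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            n = int(rng.integers(5, 60))
            scores = rng.choice([0.1, 0.2, 0.2, 0.5, 0.9, 1.3], size=n)
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            _, a = roc_auc(scores, labels)
            assert a == pytest.approx(concordance_auc(scores, labels), abs=1e-12)
            assert a == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-5, 5), min_size=4, max_size=40), st.data())
    def test_monotone_transform_invariance(self, scores, data):
        labels = data.draw(
            st.lists(st.integers(0, 1), min_size=len(scores), max_size=len(scores))
        )
        y = np.array(labels)
        if y.min() == y.max():
            return
        # round to a coarse grid so the transform cannot create new float ties
        s = np.round(np.array(scores), 3)
        _, a1 = roc_auc(s, y)
        _, a2 = roc_auc(np.exp(0.5 * s), y)  # strictly increasing transform
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_score_negation_complements_auc(self):
        rng = np.random.default_rng(2)
        s = rng.permutation(np.arange(30.0))  # tie-free
        y = rng.integers(0, 2, 30)
        y[:2] = [0, 1]
        _, a = roc_auc(s, y)
        _, b = roc_auc(-s, y)
        assert a + b == pytest.approx(1.0, abs=1e-12)


class TestTrain:
    def toy(self, n=100, seed=0):
        rng = np.random.default_rng(seed)
        y = np.repeat([0, 1], n // 2)
        X = pd.DataFrame(
            {
                "u": rng.normal(size=n) + 4.0 * y,
                "v": rng.normal(size=n) - 4.0 * y,
            }
        )
        return X, pd.Series(y)

    @pytest.mark.parametrize("family", FAMILIES)
    def test_separable_toy_reaches_perfect_train_auc(self, family):
        X, y = self.toy()
        model = train(ClassifierSpec(family, seed=0), X, y)
        _, a = roc_auc(model.scores(X), y)
        assert a == 1.0

    @pytest.mark.parametrize("family", FAMILIES)
    def test_shuffled_labels_validate_near_chance(self, family):
        X, y = self.toy(n=400, seed=3)
        rng = np.random.default_rng(7)
        y_shuf = pd.Series(rng.permutation(y.to_numpy()))
        model = train(ClassifierSpec(family, seed=0), X.iloc[:200], y_shuf.iloc[:200])
        _, a = roc_auc(model.scores(X.iloc[200:]), y_shuf.iloc[200:])
        assert abs(a - 0.5) < 0.15

    def test_refit_is_deterministic(self):
        X, y = self.toy(seed=5)
        s1 = train(ClassifierSpec("RF", seed=9), X, y).scores(X)
        s2 = train(ClassifierSpec("RF", seed=9), X, y).scores(X)
        np.testing.assert_array_equal(s1, s2)

    def test_nan_input_rejected(self):
        X, y = self.toy()
        X.iloc[0, 0] = np.nan
        with pytest.raises(ValueError):
            train(ClassifierSpec("LR"), X, y)

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            ClassifierSpec("DeepNet")


class TestSplits:
    def meta(self, n_per_class=40):
        n = 2 * n_per_class
        return pd.DataFrame(
            {
                "window_id": np.arange(n),
                "track_id": 1000 + np.arange(n),
                "label": ["alive"] * n_per_class + ["killed"] * n_per_class,
            }
        )

    def test_counts_balance_and_disjointness(self):
        plan = SplitPlan(n_train_per_class=10, n_validation_sets=3, n_val_per_class=5, seed=0)
        splits = make_splits(self.meta(40), plan)
        meta = self.meta(40).set_index("window_id")
        groups = [splits["train"], *splits["validation"]]
        assert len(splits["train"]) == 20
        for v in splits["validation"]:
            assert len(v) == 10
            assert (meta.loc[v, "label"] == "killed").sum() == 5
        all_ids = sum(groups, [])
        assert len(all_ids) == len(set(all_ids))  # mutually disjoint
        assert (meta.loc[splits["train"], "label"] == "killed").sum() == 10

    def test_insufficient_pool_rejected(self):
        plan = SplitPlan(n_train_per_class=30, n_validation_sets=3, n_val_per_class=5)
        with pytest.raises(ValueError, match="not enough"):
            make_splits(self.meta(20), plan)

    def test_duplicate_tracks_rejected(self):
        meta = self.meta(10)
        meta.loc[1, "track_id"] = meta.loc[0, "track_id"]
        with pytest.raises(ValueError, match="one window per track"):
            make_splits(meta, SplitPlan(2, 1, 2))


class TestSweep:
    def data(self, k=3, n=60, seed=0):
        rng = np.random.default_rng(seed)
        y = pd.Series(np.repeat([0, 1], n // 2), name="label")
        cols = {}
        feats = [f"f{i}" for i in range(k)]
        for i, f in enumerate(feats):
            cols[f"{f}@pct(1-2)"] = rng.normal(size=n) + (0.6 + 0.2 * i) * y
        X = pd.DataFrame(cols)
        splits = {
            "train": list(range(0, n, 2)),
            "validation": [list(range(1, n, 2))],
        }
        return X, y, feats, splits

    @pytest.mark.parametrize("k,expected", [(1, 1), (3, 7)])
    def test_result_count_is_all_nonempty_subsets(self, k, expected):
        X, y, feats, splits = self.data(k=k)
        res = sweep(X, y, feats, "P1", "Bayes", splits, seed=0)
        assert len(res) == expected
        assert sorted(r.subset_mask for r in res) == list(range(1, 2**k))

    def test_subset_masks_map_to_feature_lists(self):
        X, y, feats, splits = self.data(k=3)
        res = sweep(X, y, feats, "P1", "LR", splits, seed=0)
        by_mask = {r.subset_mask: r.feature_subset for r in res}
        assert by_mask[0b101] == ["f0", "f2"]
        assert by_mask[0b111] == feats

    def test_total_grid_size(self):
        X, y, feats, splits = self.data(k=2)
        total = []
        for fam in ("Bayes", "LR"):
            for itype in ("P1",):
                total += sweep(X, y, feats, itype, fam, splits, seed=0)
        assert len(total) == 2 * 1 * (2**2 - 1)

    def test_subset_columns_for_two_block_input(self):
        cols = ["a@pct(1-2)", "b@pct(1-2)", "a@pct(2-3)", "b@pct(2-3)"]
        assert subset_columns(cols, ["a"]) == ["a@pct(1-2)", "a@pct(2-3)"]


class TestCompareInputs:
    def result(self, fam="RF", itype="P2", mask=1, auc=0.9, vals=(0.8,)):
        return SweepResult(fam, itype, mask, [f"f{mask}"], auc, list(vals))

    def test_all_equal_aucs_pick_lowest_mask(self):
        res = [self.result(mask=m, auc=0.7) for m in (1, 2, 3)]
        summary, top = compare_inputs(res)
        assert top.subset_mask == 1
        assert summary["sd_auc"].iloc[0] == 0.0

    def test_single_result_summary_equals_it(self):
        summary, top = compare_inputs([self.result(auc=0.88)])
        assert summary["mean_auc"].iloc[0] == pytest.approx(0.88)
        assert top.train_auc == 0.88

    def test_tie_prefers_fewer_features(self):
        a = SweepResult("RF", "P2", 0b11, ["f0", "f1"], 0.9, [0.9])
        b = SweepResult("RF", "P2", 0b100, ["f2"], 0.9, [0.9])
        _, top = compare_inputs([a, b])
        assert top is b
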