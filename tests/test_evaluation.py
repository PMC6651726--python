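"""Metrics, ROC/AUC, cross-validation folds, and sweeps."""

import numpy as np
import pytest

from neurobrake import PipelineConfig, confusion_metrics, kfold_cv, roc_curve_auc
from neurobrake.core import DatasetTable
from neurobrake.evaluation import sweep


def mann_whitney_auc(y, s):
    """Brute-force pairwise AUC oracle (ties count 1/2)."""
    y, s = np.asarray(y), np.asarray(s)
    pos, neg = s[y == 1], s[y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestConfusionMetrics:
    def test_perfect_classifier(self):
        y = np.r_[np.ones(50, int), np.zeros(50, int)]
        m = confusion_metrics(y, y)
        assert (m.accuracy, m.sensitivity, m.specificity) == (1.0, 1.0, 1.0)

    def test_all_negative_predictions(self):
        y_true = np.r_[np.ones(10, int), np.zeros(90, int)]
        m = confusion_metrics(y_true, np.zeros(100, int))
        assert m.sensitivity == 0.0
        assert m.specificity == 1.0
        assert m.accuracy == pytest.approx(0.9)

    def test_matches_direct_pair_counting(self, rng):
        y_true = rng.integers(0, 2, 200)
        y_pred = rng.integers(0, 2, 200)
        m = confusion_metrics(y_true, y_pred)
        tp = int(np.sum((y_true == 1) & (y_pred == 1)))
        tn = int(np.sum((y_true == 0) & (y_pred == 0)))
        assert m.confusion.tp == tp and m.confusion.tn == tn
        assert m.confusion.total == 200
        assert m.accuracy == pytest.approx((tp + tn) / 200)

    def test_undefined_marked_not_nan(self):
        m = confusion_metrics([0, 0, 0], [0, 1, 0])
        assert m.sensitivity is None  # no positives in truth
        assert m.specificity == pytest.approx(2 / 3)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics([], [])


class TestRocAuc:
    def test_perfect_separation_gives_one(self):
        y = np.r_[np.zeros(20, int), np.ones(20, int)]
        s = np.r_[np.linspace(0, 0.4, 20), np.linspace(0.6, 1, 20)]
        assert roc_curve_auc(y, s)[2] == pytest.approx(1.0)

    def test_random_scores_near_half(self, rng):
        y = rng.integers(0, 2, 2000)
        s = rng.random(2000)
        assert abs(roc_curve_auc(y, s)[2] - 0.5) < 0.05

    def test_equals_mann_whitney_with_ties(self, rng):
        y = rng.integers(0, 2, 30)
        y[:2] = [0, 1]
        s = np.round(rng.random(30), 1)  # force ties
        assert roc_curve_auc(y, s)[2] == pytest.approx(
            mann_whitney_auc(y, s), abs=1e-12
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve_auc(np.ones(5, int), np.random.rand(5))


def separable_table(n0, n1, d=6, seed=0, groups=None):
    rng = np.random.default_rng(seed)
    x = np.vstack(
        [rng.normal(-1, 1, (n0, d)), rng.normal(1, 1, (n1, d))]
    )
    y = np.r_[np.zeros(n0, int), np.ones(n1, int)]
    return DatasetTable(features=x, labels=y, groups=groups)


class TestKFold:
    def test_fold_sizes_for_922_496_split(self):
        """1418 samples at the recorded 922/496 class split give
        validation folds {284, 284, 284, 283, 283}."""
        table = separable_table(922, 496)
        cfg = PipelineConfig(n_hidden=5, max_iterations=5)
        res = kfold_cv(table, k=5, config=cfg, seed=0)
        sizes = sorted(f.n_val for f in res.folds)
        assert sizes == [283, 283, 284, 284, 284]

    def test_every_sample_validated_once_and_deterministic(self):
        from sklearn.model_selection import StratifiedKFold

        table = separable_table(60, 40)
        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=3)
        seen = np.zeros(100, int)
        for _, val in skf.split(table.features, table.labels):
            seen[val] += 1
        assert np.all(seen == 1)
        r1 = kfold_cv(table, k=5, config=PipelineConfig(n_hidden=4, max_iterations=5), seed=3)
        r2 = kfold_cv(table, k=5, config=PipelineConfig(n_hidden=4, max_iterations=5), seed=3)
        assert [f.metrics.accuracy for f in r1.folds] == [
            f.metrics.accuracy for f in r2.folds
        ]

    def test_stratification_preserves_class_ratio(self):
        table = separable_table(90, 60)
        cfg = PipelineConfig(n_hidden=4, max_iterations=5)
        res = kfold_cv(table, k=5, config=cfg, seed=0)
        for f in res.folds:
            # 60/40 split within one sample per fold of 30
            assert f.metrics.confusion.tp + f.metrics.confusion.fn in (12,)
        assert res.pooled.confusion.total == 150

    def test_groups_never_split_across_folds(self):
        from sklearn.model_selection import StratifiedGroupKFold

        groups = np.repeat(np.arange(20), 5)
        y = np.repeat(np.arange(20) % 2, 5)
        x = np.random.default_rng(0).standard_normal((100, 3))
        skf = StratifiedGroupKFold(n_splits=5, shuffle=True, random_state=0)
        for tr, va in skf.split(x, y, groups):
            assert not set(groups[tr]) & set(groups[va])

    def test_k_exceeding_class_count_rejected(self):
        table = separable_table(50, 3)
        with pytest.raises(ValueError):
            kfold_cv(table, k=5, config=PipelineConfig(n_hidden=4), seed=0)


class TestSweep:
    def test_single_value_matches_plain_cv(self, session600, ar_config):
        from neurobrake.pipeline import build_dataset

        sw = sweep("n_hidden", [20], session600, ar_config, k=5, seed=0)
        table = build_dataset(session600, ar_config)
        from neurobrake.pipeline import with_params

        direct = kfold_cv(table, k=5, config=with_params(ar_config, n_hidden=20), seed=0)
        assert sw.results[0].mean_accuracy == pytest.approx(direct.mean_accuracy)

    def test_empty_grid_rejected(self, session600, ar_config):
        with pytest.raises(ValueError):
            sweep("ar_order", [], session600, ar_config)

    def test_unknown_parameter_rejected(self, session600, ar_config):
        with pytest.raises(ValueError):
            sweep("dropout", [0.1], session600, ar_config)

    def test_to_frame_layout(self, session600, ar_config):
        sw = sweep("n_hidden", [10, 20], session600, ar_config, k=3, seed=0)
        frame = sw.to_frame()
        assert list(frame["n_hidden"]) == [10, 20]
        assert {"mean_accuracy", "mean_auc", "sd_accuracy"} <= set(frame.columns)
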