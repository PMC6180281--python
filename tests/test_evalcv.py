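import numpy as np
import pandas as pd
import pytest

from eegcomplex import (
    AnalysisConfig,
    ClassifyConfig,
    confusion_metrics,
    loso_folds,
    roc_auc,
    run_loso,
)
from eegcomplex.evalcv import metrics_row
from eegcomplex.mse import feature_names
from eegcomplex.montage import CHANNELS_1020


def brute_force_auc(y, scores):
    pos = [s for s, t in zip(scores, y) if t == 1]
    neg = [s for s, t in zip(scores, y) if t == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            total += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
    return total / (len(pos) * len(neg))


def synthetic_feature_table(n_subjects, effect=0.0, sessions=3, seed=0):
    """Feature table with optional group mean-shift on the first features."""
    rng = np.random.default_rng(seed)
    names = feature_names(CHANNELS_1020, 20)
    rows, meta = [], []
    for i in range(n_subjects):
        group = "HC" if i < n_subjects // 2 else "AD3"
        shift = np.zeros(len(names))
        if group == "AD3":
            shift[:10] = effect
        for s in range(sessions):
            rows.append(rng.standard_normal(len(names)) + shift)
            meta.append((f"sub{i:03d}", f"s{s + 1}", group))
    table = pd.DataFrame(meta, columns=["subject_id", "session_id", "group"])
    return pd.concat([table, pd.DataFrame(rows, columns=names)], axis=1)


class TestLosoFolds:
    def test_basic_shape(self):
        groups = np.repeat([f"s{i}" for i in range(5)], 3)
        folds = loso_folds(groups)
        assert len(folds) == 5
        assert all(len(test) == 3 for _, test in folds)

    def test_partition_property(self):
        groups = np.repeat([f"s{i}" for i in range(7)], 3)
        folds = loso_folds(groups)
        all_test = np.concatenate([test for _, test in folds])
        assert sorted(all_test.tolist()) == list(range(21))
        for train, test in folds:
            assert not set(train) & set(test)
            assert len(train) + len(test) == 21

    def test_order_independent_of_input_order(self, rng):
        groups = np.repeat([f"s{i}" for i in range(4)], 2)
        perm = rng.permutation(len(groups))
        folds_a = loso_folds(groups)
        folds_b = loso_folds(groups[perm])
        subj_a = [set(groups[t]) for _, t in folds_a]
        subj_b = [set(groups[perm][t]) for _, t in folds_b]
        assert subj_a == subj_b

    def test_needs_two_subjects(self):
        with pytest.raises(ValueError):
            loso_folds(["a", "a", "a"])


class TestConfusionMetrics:
    def test_worked_example(self):
        # TP=9, FN=1, TN=8, FP=2
        y_true = ["P"] * 10 + ["N"] * 10
        y_pred = ["P"] * 9 + ["N"] + ["P"] * 2 + ["N"] * 8
        m = confusion_metrics(y_true, y_pred, positive="P")
        assert (m.tp, m.fn, m.fp, m.tn) == (9, 1, 2, 8)
        assert m.sensitivity == pytest.approx(0.90)
        assert m.specificity == pytest.approx(0.80)
        assert m.accuracy == pytest.approx(0.85)

    def test_all_correct(self):
        y = ["P", "N", "P", "N"]
        m = confusion_metrics(y, y, positive="P")
        assert m.sensitivity == m.specificity == m.accuracy == 1.0

    def test_chance_level_under_permutation(self, rng):
        n = 20_000
        y = np.array(["P", "N"])[rng.integers(0, 2, n)]
        pred = np.array(["P", "N"])[rng.integers(0, 2, n)]
        m = confusion_metrics(y, pred, positive="P")
        se = np.sqrt(0.25 / n)
        assert abs(m.accuracy - 0.5) < 4 * se

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics([], [], positive="P")


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_all_ties(self):
        assert roc_auc([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5]) == 0.5

    def test_matches_brute_force(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 30))
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                continue
            scores = np.round(rng.random(n), 1)  # rounded: force some ties
            assert roc_auc(y, scores) == pytest.approx(brute_force_auc(y, scores))

    def test_single_class_undefined(self):
        assert np.isnan(roc_auc([1, 1, 1], [0.1, 0.2, 0.3]))


class TestRunLoso:
    def test_unregularized_lr_overfits_p_gt_n(self):
        table = synthetic_feature_table(10, effect=0.0, seed=1)
        cfg = AnalysisConfig(classify=ClassifyConfig(method="lr"), seed=0)
        with pytest.warns(RuntimeWarning):
            cv, metrics = run_loso(table, cfg)
        assert cv.mean_train_accuracy == 1.0

    def test_no_leakage_bookkeeping(self):
        table = synthetic_feature_table(8, effect=2.0, seed=2)
        cfg = AnalysisConfig(
            classify=ClassifyConfig(method="lasso", lambda_grid_size=10, inner_folds=2),
            seed=0,
        )
        cv, metrics = run_loso(table, cfg)
        subjects = table["subject_id"].unique()
        tested = [f.test_subject for f in cv.folds]
        assert sorted(tested) == sorted(subjects)  # each subject tested once
        assert len(cv.pooled_proba) == len(table)
        assert not np.isnan(cv.pooled_proba).any()
        all_test = np.concatenate([f.test_index for f in cv.folds])
        assert sorted(all_test.tolist()) == list(range(len(table)))
        for fold in cv.folds:
            assert set(fold.selected_features) <= set(cv.feature_names)
            assert fold.lam > 0

    def test_strong_effect_recovered(self):
        table = synthetic_feature_table(10, effect=3.0, seed=3)
        cfg = AnalysisConfig(
            classify=ClassifyConfig(method="lasso", lambda_grid_size=15, inner_folds=3),
            seed=0,
        )
        cv, metrics = run_loso(table, cfg)
        assert metrics.accuracy > 0.9
        assert metrics.auc > 0.95

    def test_null_effect_no_spurious_skill(self):
        # With no planted effect the classifier must show no skill.  Note
        # LOSO with balanced groups is anti-biased under the null (the test
        # subject is always the training minority class, and the null model
        # predicts the training majority), so accuracy lands at or *below*
        # chance; the one-sided bound is the meaningful check.
        accs, aucs = [], []
        for seed in (4, 5, 6):
            table = synthetic_feature_table(12, effect=0.0, seed=seed)
            cfg = AnalysisConfig(
                classify=ClassifyConfig(method="lasso", lambda_grid_size=10, inner_folds=3),
                seed=0,
            )
            cv, metrics = run_loso(table, cfg)
            accs.append(metrics.accuracy)
            aucs.append(metrics.auc)
        n = 36
        se = np.sqrt(0.25 / n)
        assert np.mean(accs) <= 0.5 + 3 * se
        assert np.mean(aucs) <= 0.5 + 3 * np.sqrt(1 / 12 / n)

    def test_positive_class_is_more_severe(self):
        table = synthetic_feature_table(8, effect=2.0, seed=5)
        cfg = AnalysisConfig(
            contrast=("AD3", "HC"),  # deliberately reversed
            classify=ClassifyConfig(method="lasso", lambda_grid_size=8, inner_folds=2),
            seed=0,
        )
        cv, _ = run_loso(table, cfg)
        assert cv.positive == "AD3"
        assert cv.contrast == ("HC", "AD3")

    def test_missing_rows_dropped_with_warning(self):
        table = synthetic_feature_table(8, effect=2.0, seed=6)
        table.iloc[0, 5] = np.nan
        cfg = AnalysisConfig(
            classify=ClassifyConfig(method="lasso", lambda_grid_size=8, inner_folds=2),
            seed=0,
        )
        with pytest.warns(RuntimeWarning, match="missing"):
            cv, _ = run_loso(table, cfg)
        assert len(cv.pooled_proba) == len(table) - 1

    def test_metrics_row_percent_scale(self):
        table = synthetic_feature_table(8, effect=3.0, seed=7)
        cfg = AnalysisConfig(
            classify=ClassifyConfig(method="lasso", lambda_grid_size=8, inner_folds=2),
            seed=0,
        )
        cv, metrics = run_loso(table, cfg)
        row = metrics_row("lasso", cv.contrast, metrics, cv.mean_train_accuracy)
        assert row["test_accuracy_pct"] == pytest.approx(100 * metrics.accuracy)
        assert row["contrast"] == "HC vs AD3"
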