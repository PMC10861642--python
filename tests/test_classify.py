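"""Splitting, SVM fitting, the metric battery, Dice, ROC/AUC, learning curves."""

import warnings

import numpy as np
import pytest

from tumortex import (
    ConfusionMatrix,
    FeatureTable,
    SplitSpec,
    dice_per_class,
    evaluate,
    fit_linear_svm,
    learning_curve,
    metrics_from_confusion,
    roc_ovr,
    stratified_split,
)
from tumortex.classify import confusion_from_predictions, decision_scores, predict


def make_table(X, labels, prefix="f"):
    X = np.asarray(X, dtype=float)
    return FeatureTable(
        source_ids=[f"s{i}" for i in range(len(labels))],
        labels=list(labels),
        values=X,
        column_names=[f"{prefix}{j}" for j in range(X.shape[1])],
    )


@pytest.fixture
def separable_toy(rng):
    """Two tight 2-D clusters at (0,0) and (10,10)."""
    a = rng.normal(0, 0.1, size=(20, 2))
    b = rng.normal(10, 0.1, size=(20, 2))
    return make_table(np.vstack([a, b]), ["a"] * 20 + ["b"] * 20)


@pytest.fixture
def three_class_toy(rng):
    centers = {"a": (0, 0), "b": (8, 0), "c": (0, 8)}
    X, y = [], []
    for label, (cx, cy) in centers.items():
        X.append(rng.normal((cx, cy), 0.3, size=(30, 2)))
        y += [label] * 30
    return make_table(np.vstack(X), y)


class TestStratifiedSplit:
    def test_proportions_preserved(self, rng):
        labels = ["a"] * 34 + ["b"] * 33 + ["c"] * 33
        table = make_table(rng.standard_normal((100, 3)), labels)
        train, test = stratified_split(table, SplitSpec(test_fraction=0.2, seed=0))
        assert len(train) == 80 and len(test) == 20
        for cls, total in (("a", 34), ("b", 33), ("c", 33)):
            n_test = test.labels.count(cls)
            assert abs(n_test - 0.2 * total) <= 1

    def test_partition_disjoint_exhaustive(self, rng):
        table = make_table(rng.standard_normal((40, 2)), ["a", "b"] * 20)
        train, test = stratified_split(table, SplitSpec(seed=3))
        assert sorted(train.source_ids + test.source_ids) == sorted(table.source_ids)
        assert not set(train.source_ids) & set(test.source_ids)

    def test_same_seed_identical(self, rng):
        table = make_table(rng.standard_normal((40, 2)), ["a", "b"] * 20)
        s1 = stratified_split(table, SplitSpec(seed=7))
        s2 = stratified_split(table, SplitSpec(seed=7))
        assert s1[0].source_ids == s2[0].source_ids
        assert s1[1].source_ids == s2[1].source_ids

    def test_small_class_rejected(self, rng):
        table = make_table(rng.standard_normal((5, 2)), ["a", "a", "a", "a", "b"])
        with pytest.raises(ValueError, match="at least 2"):
            stratified_split(table, SplitSpec())

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1])
    def test_bad_fraction_rejected(self, bad):
        with pytest.raises(ValueError, match="test_fraction"):
            SplitSpec(test_fraction=bad)


class TestFitLinearSVM:
    def test_separable_training_accuracy(self, separable_toy):
        model = fit_linear_svm(separable_toy, seed=0)
        preds = predict(model, separable_toy)
        assert preds == separable_toy.labels

    def test_duplication_leaves_decisions(self, separable_toy):
        """Duplicating every training point leaves the decision boundary in
        place (the regularized optimum shifts only slightly, predictions not
        at all on well-separated data)."""
        model = fit_linear_svm(separable_toy, seed=0)
        doubled = separable_toy.subset(list(range(40)) * 2)
        model2 = fit_linear_svm(doubled, seed=0)
        assert predict(model, separable_toy) == predict(model2, separable_toy)
        s1 = decision_scores(model, separable_toy)
        s2 = decision_scores(model2, separable_toy)
        np.testing.assert_allclose(s1, s2, rtol=0.05)

    def test_single_class_rejected(self, rng):
        table = make_table(rng.standard_normal((10, 2)), ["a"] * 10)
        with pytest.raises(ValueError, match="2 classes"):
            fit_linear_svm(table)

    def test_layout_mismatch_rejected(self, separable_toy, rng):
        model = fit_linear_svm(separable_toy, seed=0)
        other = make_table(rng.standard_normal((4, 2)), ["a", "b", "a", "b"], prefix="g")
        with pytest.raises(ValueError, match="layout"):
            predict(model, other)

    def test_three_class_holdout(self, three_class_toy):
        train, test = stratified_split(three_class_toy, SplitSpec(seed=1))
        model = fit_linear_svm(train, seed=1)
        _, report = evaluate(model, test)
        assert report.macro["f1"] >= 0.95


def random_confusion(rng, max_k=5):
    k = int(rng.integers(2, max_k + 1))
    counts = rng.integers(0, 30, size=(k, k))
    if counts.sum() == 0:
        counts[0, 0] = 1
    return ConfusionMatrix(counts=counts, labels=tuple(f"c{i}" for i in range(k)))


class TestMetrics:
    def test_binary_hand_example(self):
        """TP=50, TN=40, FP=5, FN=5 for the positive class."""
        cm = ConfusionMatrix(counts=np.array([[50, 5], [5, 40]]), labels=("pos", "neg"))
        rep = metrics_from_confusion(cm)
        pos = 0
        assert rep.per_class["accuracy"][pos] == pytest.approx(0.9)
        assert rep.per_class["precision"][pos] == pytest.approx(50 / 55)
        assert rep.per_class["recall"][pos] == pytest.approx(50 / 55)
        assert rep.per_class["specificity"][pos] == pytest.approx(40 / 45)
        assert rep.per_class["fpr"][pos] == pytest.approx(5 / 45)

    def test_perfect_predictions(self):
        cm = ConfusionMatrix(counts=np.diag([10, 12, 8]), labels=("a", "b", "c"))
        rep = metrics_from_confusion(cm)
        for key in ("accuracy", "precision", "recall", "f1", "specificity"):
            assert rep.macro[key] == pytest.approx(1.0)
        assert rep.macro["fpr"] == 0 and rep.macro["fnr"] == 0
        assert rep.micro_accuracy == 1.0

    def test_constant_predictor_on_balanced_classes(self):
        counts = np.zeros((3, 3), dtype=int)
        counts[:, 0] = 10  # everything predicted as the first class
        rep = metrics_from_confusion(ConfusionMatrix(counts=counts, labels=("a", "b", "c")))
        assert rep.micro_accuracy == pytest.approx(1 / 3)

    def test_identities_on_fuzzed_matrices(self, rng):
        for _ in range(500):
            cm = random_confusion(rng)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rep = metrics_from_confusion(cm)
            pc = rep.per_class
            np.testing.assert_array_equal(pc["recall"], pc["sensitivity"])
            np.testing.assert_array_equal(pc["recall"], pc["tpr"])
            np.testing.assert_allclose(pc["fnr"], 1 - pc["tpr"], atol=1e-12)
            np.testing.assert_allclose(pc["specificity"], 1 - pc["fpr"], atol=1e-12)
            np.testing.assert_array_equal(pc["specificity"], pc["tnr"])
            tp, fp, fn, tn = cm.one_vs_rest()
            assert np.all(tp + fp + fn + tn == cm.total)
            assert rep.micro_accuracy == pytest.approx(np.trace(cm.counts) / cm.total)

    def test_dice_equals_f1_on_fuzzed_matrices(self, rng):
        for _ in range(100):
            cm = random_confusion(rng)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rep = metrics_from_confusion(cm)
                dice, _ = dice_per_class(cm)
            defined = (2 * np.diag(cm.counts) + cm.counts.sum(0) - np.diag(cm.counts)
                       + cm.counts.sum(1) - np.diag(cm.counts)) > 0
            np.testing.assert_allclose(dice[defined], rep.per_class["f1"][defined], atol=1e-12)

    def test_dice_hand_example(self):
        cm = ConfusionMatrix(counts=np.array([[50, 5], [5, 40]]), labels=("p", "n"))
        dice, macro = dice_per_class(cm)
        assert dice[0] == pytest.approx(100 / 110)

    def test_dice_empty_class_warns(self):
        counts = np.array([[5, 0, 0], [0, 5, 0], [0, 0, 0]])
        cm = ConfusionMatrix(counts=counts, labels=("a", "b", "c"))
        with pytest.warns(UserWarning, match="empty-vs-empty"):
            dice, _ = dice_per_class(cm)
        assert dice[2] == 1.0


def brute_force_auc(scores_pos, scores_neg):
    """Pairwise win rate: ties count half."""
    wins = 0.0
    for p in scores_pos:
        for n in scores_neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(scores_pos) * len(scores_neg))


class TestROC:
    def test_perfect_separation(self):
        y = ["pos"] * 5 + ["neg"] * 5
        s = np.array([2.0] * 5 + [-2.0] * 5)
        scores = np.column_stack([-s, s])
        roc = roc_ovr(scores, y, ("neg", "pos"))
        assert roc.auc_per_class["pos"] == 1.0
        assert roc.auc_per_class["neg"] == 1.0
        assert roc.auc_micro == 1.0

    def test_four_point_hand_example(self):
        """Positives 0.9/0.8, negatives 0.7/0.95: 2 wins of 4 pairs -> 0.5."""
        y = ["pos", "pos", "neg", "neg"]
        s = np.array([0.9, 0.8, 0.7, 0.95])
        roc = roc_ovr(np.column_stack([-s, s]), y, ("neg", "pos"))
        assert roc.auc_per_class["pos"] == pytest.approx(0.5)
        assert roc.auc_per_class["pos"] == pytest.approx(
            brute_force_auc([0.9, 0.8], [0.7, 0.95])
        )

    def test_label_independent_scores_near_half(self, rng):
        n = 4000
        y = np.where(rng.random(n) < 0.5, "pos", "neg")
        s = rng.standard_normal(n)
        roc = roc_ovr(np.column_stack([-s, s]), y, ("neg", "pos"))
        assert roc.auc_per_class["pos"] == pytest.approx(0.5, abs=0.05)

    def test_matches_pairwise_oracle_small_inputs(self, rng):
        for _ in range(25):
            n = int(rng.integers(4, 51))
            y = rng.choice(["a", "b", "c"], size=n)
            if len(set(y)) < 3:
                continue
            scores = np.round(rng.standard_normal((n, 3)), 1)  # rounded to force ties
            roc = roc_ovr(scores, y, ("a", "b", "c"))
            for k, label in enumerate(("a", "b", "c")):
                pos = scores[y == label, k]
                neg = scores[y != label, k]
                assert roc.auc_per_class[label] == pytest.approx(
                    brute_force_auc(pos, neg), abs=1e-10
                )

    def test_micro_pools_all_pairs(self, rng):
        n = 30
        y = rng.choice(["a", "b"], size=n)
        while len(set(y)) < 2:
            y = rng.choice(["a", "b"], size=n)
        scores = rng.standard_normal((n, 2))
        roc = roc_ovr(scores, y, ("a", "b"))
        pooled_pos = np.concatenate([scores[y == "a", 0], scores[y == "b", 1]])
        pooled_neg = np.concatenate([scores[y != "a", 0], scores[y != "b", 1]])
        assert roc.auc_micro == pytest.approx(brute_force_auc(pooled_pos, pooled_neg), abs=1e-10)

    def test_degenerate_class_warns(self):
        y = ["a", "a", "b", "b"]
        scores = np.zeros((4, 3))
        with pytest.warns(UserWarning, match="AUC undefined"):
            roc = roc_ovr(scores, y, ("a", "b", "c"))
        assert np.isnan(roc.auc_per_class["c"])


class TestLearningCurve:
    def test_separable_perfect_train_score_at_every_size(self, three_class_toy):
        lc = learning_curve(three_class_toy, [0.3, 0.6, 1.0], SplitSpec(folds=3, seed=0))
        assert set(lc) == {0.3, 0.6, 1.0}
        for size, scores in lc.items():
            assert scores["train_mean"] == 1.0
            assert scores["train_sd"] == 0.0
            assert 0.0 <= scores["val_sd"]

    def test_validation_high_on_separable(self, three_class_toy):
        lc = learning_curve(three_class_toy, [1.0], SplitSpec(folds=3, seed=0))
        assert lc[1.0]["val_mean"] >= 0.95

    def test_deterministic(self, three_class_toy):
        spec = SplitSpec(folds=3, seed=5)
        assert learning_curve(three_class_toy, [0.5, 1.0], spec) == learning_curve(
            three_class_toy, [0.5, 1.0], spec
        )

    def test_tiny_size_skipped_with_warning(self, three_class_toy):
        with pytest.warns(UserWarning, match="skipped"):
            lc = learning_curve(three_class_toy, [0.01, 1.0], SplitSpec(folds=3, seed=0))
        assert 0.01 not in lc and 1.0 in lc

    def test_bad_size_rejected(self, three_class_toy):
        with pytest.raises(ValueError, match="sizes"):
            learning_curve(three_class_toy, [0.0], SplitSpec())


class TestEvaluate:
    def test_confusion_totals(self, three_class_toy):
        train, test = stratified_split(three_class_toy, SplitSpec(seed=2))
        model = fit_linear_svm(train, seed=2)
        cm, report = evaluate(model, test)
        assert cm.total == len(test)
        assert set(report.auc_per_class) == {"a", "b", "c"}

    def test_confusion_from_predictions_counts(self):
        cm = confusion_from_predictions(
            ["a", "a", "b", "b"], ["a", "b", "b", "b"], ["a", "b"]
        )
        np.testing.assert_array_equal(cm.counts, [[1, 1], [0, 2]])
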