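"""Splitting, loss, training loop, grid search, and evaluation metrics."""

import numpy as np
import pytest
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support

import fhpose as f
from fhpose.errors import ValidationError


def make_gcn(seed=0, dropout=0.0):
    cfg = f.GCNConfig(dropout_rate=dropout)
    return f.GCNClassifier(f.build_upper_body_graph().adjacency, cfg, seed=seed)


def shaped_splits(dataset, kind="gcn", seed=0):
    tr, va, te = f.split_dataset(dataset, seed=seed)
    return [(f.poses_to_model_inputs(part.poses, kind), part.labels)
            for part in (tr, va, te)]


class TestSplit:
    def test_100_samples_split_70_15_15(self):
        labels = np.array([0] * 64 + [1] * 36)
        tr, va, te = f.stratified_split_indices(labels, seed=0)
        assert (len(tr), len(va), len(te)) == (70, 15, 15)
        union = np.concatenate([tr, va, te])
        assert len(np.unique(union)) == 100  # disjoint + exhaustive

    def test_small_balanced_split_keeps_both_classes(self):
        labels = np.array([0, 1] * 10)
        tr, va, te = f.stratified_split_indices(labels, seed=3)
        assert (len(tr), len(va), len(te)) == (14, 3, 3)
        for part in (tr, va, te):
            assert set(labels[part]) == {0, 1}

    def test_stratification_preserves_class_ratio(self):
        labels = np.array([0] * 640 + [1] * 360)
        tr, va, te = f.stratified_split_indices(labels, seed=1)
        for part in (tr, va, te):
            frac = np.mean(labels[part])
            assert abs(frac - 0.36) < 0.02

    def test_same_seed_identical_indices(self):
        labels = np.array([0] * 30 + [1] * 20)
        a = f.stratified_split_indices(labels, seed=5)
        b = f.stratified_split_indices(labels, seed=5)
        for x, y in zip(a, b):
            assert np.array_equal(x, y)

    def test_bad_ratios_rejected(self):
        with pytest.raises(ValidationError):
            f.stratified_split_indices(np.zeros(20, dtype=int), ratios=(0.5, 0.3, 0.3))


class TestCrossEntropy:
    def test_perfect_prediction_zero_loss(self):
        assert f.cross_entropy([1.0, 0.0], [1.0, 0.0]) == pytest.approx(0.0)

    def test_uniform_prediction_ln2(self):
        assert f.cross_entropy([0.5, 0.5], [0.0, 1.0]) == pytest.approx(np.log(2))

    def test_zero_probability_clamped_not_infinite(self):
        loss = f.cross_entropy([0.0, 1.0], [1.0, 0.0])
        assert np.isfinite(loss)
        assert loss == pytest.approx(-np.log(1e-12))

    def test_batch_mean_matches_per_sample_loop(self, rng):
        probs = rng.dirichlet([1, 1], size=12)
        labels = rng.integers(0, 2, size=12)
        targets = f.one_hot(labels)
        expected = np.mean([-np.log(max(probs[i, labels[i]], 1e-12))
                            for i in range(12)])
        assert f.cross_entropy(probs, targets) == pytest.approx(expected)

    def test_invalid_probs_rejected(self):
        with pytest.raises(ValidationError):
            f.cross_entropy([0.9, 0.9], [1.0, 0.0])


class TestTrainModel:
    def test_separable_noiseless_data_reaches_full_training_accuracy(
            self, noiseless_dataset):
        (Xtr, ytr), (Xva, yva), _ = shaped_splits(noiseless_dataset)
        model = make_gcn(seed=0)
        cfg = f.TrainConfig(seed=0, max_epochs=200)
        _, history = f.train_model(model, (Xtr, ytr), (Xva, yva), cfg)
        assert max(history["train_acc"]) == 1.0

    def test_zero_learning_rate_leaves_weights_unchanged(self, small_dataset):
        (Xtr, ytr), (Xva, yva), _ = shaped_splits(small_dataset)
        model = make_gcn(seed=1)
        before = model.get_params()
        cfg = f.TrainConfig(seed=1, learning_rate=0.0, max_epochs=3, patience=5)
        f.train_model(model, (Xtr, ytr), (Xva, yva), cfg)
        for k in before:
            assert np.array_equal(model.params[k], before[k])

    def test_fixed_seed_identical_history(self, small_dataset):
        (Xtr, ytr), (Xva, yva), _ = shaped_splits(small_dataset)
        histories = []
        for _ in range(2):
            model = make_gcn(seed=2)
            cfg = f.TrainConfig(seed=2, max_epochs=8, patience=10)
            _, h = f.train_model(model, (Xtr, ytr), (Xva, yva), cfg)
            histories.append(h)
        assert histories[0]["val_loss"] == histories[1]["val_loss"]
        assert histories[0]["train_loss"] == histories[1]["train_loss"]

    def test_empty_split_rejected(self, small_dataset):
        (Xtr, ytr), _, _ = shaped_splits(small_dataset)
        with pytest.raises(ValidationError):
            f.train_model(make_gcn(), (Xtr, ytr), (Xtr[:0], ytr[:0]))


class TestGridSearch:
    def factory(self):
        def make(rate, seed):
            return make_gcn(seed=seed, dropout=rate)
        return make

    def test_single_value_grid_returns_it(self, small_dataset):
        (Xtr, ytr), (Xva, yva), _ = shaped_splits(small_dataset)
        cfg = f.TrainConfig(seed=0, max_epochs=3, patience=5, dropout_grid=(0.3,))
        best, table = f.grid_search_dropout(self.factory(), (Xtr, ytr), (Xva, yva), cfg)
        assert best == 0.3
        assert len(table) == 1

    def test_two_value_grid_winner_has_max_val_accuracy(self, noiseless_dataset):
        (Xtr, ytr), (Xva, yva), _ = shaped_splits(noiseless_dataset)
        cfg = f.TrainConfig(seed=0, max_epochs=25, patience=25,
                            dropout_grid=(0.0, 0.9))
        best, table = f.grid_search_dropout(self.factory(), (Xtr, ytr), (Xva, yva), cfg)
        assert len(table) == 2
        winner = next(r for r in table if r["dropout_rate"] == best)
        assert all(winner["val_accuracy"] >= r["val_accuracy"] for r in table)

    def test_selection_equals_manual_argmax_with_tie_to_lowest(self, small_dataset):
        (Xtr, ytr), (Xva, yva), _ = shaped_splits(small_dataset)
        cfg = f.TrainConfig(seed=4, max_epochs=4, patience=6,
                            dropout_grid=(0.0, 0.2, 0.4))
        best, table = f.grid_search_dropout(self.factory(), (Xtr, ytr), (Xva, yva), cfg)
        top = max(r["val_accuracy"] for r in table)
        expected = min(r["dropout_rate"] for r in table if r["val_accuracy"] == top)
        assert best == expected

    def test_empty_grid_rejected(self, small_dataset):
        (Xtr, ytr), (Xva, yva), _ = shaped_splits(small_dataset)
        cfg = f.TrainConfig(dropout_grid=())
        with pytest.raises(ValidationError):
            f.grid_search_dropout(self.factory(), (Xtr, ytr), (Xva, yva), cfg)


class TestEvaluate:
    def test_all_correct_predictions(self):
        report = f.report_from_predictions([0, 1] * 5, [0, 1] * 5)
        assert report.accuracy == 1.0
        assert report.macro_f1 == 1.0
        assert np.trace(report.confusion_matrix) == 10

    def test_f1_is_harmonic_mean_of_printed_precision_recall(self):
        # 81.99% precision with 81.22% recall gives an F1 of 81.60%.
        p, r = 0.8199, 0.8122
        f1 = 2 * p * r / (p + r)
        assert round(100 * f1, 2) == 81.60

    def test_report_matches_loop_counting_oracle(self, rng):
        y_true = rng.integers(0, 2, size=200)
        y_pred = rng.integers(0, 2, size=200)
        report = f.report_from_predictions(y_true, y_pred)
        counts = np.zeros((2, 2))
        for t, p in zip(y_true, y_pred):   # loop-counting oracle
            counts[t, p] += 1
        assert np.array_equal(report.confusion_matrix, counts)
        for c in range(2):
            tp = counts[c, c]
            assert report.precision[c] == pytest.approx(tp / counts[:, c].sum())
            assert report.recall[c] == pytest.approx(tp / counts[c, :].sum())
        assert report.accuracy == pytest.approx(np.trace(counts) / 200)

    def test_report_agrees_with_sklearn(self, rng):
        y_true = rng.integers(0, 2, size=150)
        y_pred = rng.integers(0, 2, size=150)
        report = f.report_from_predictions(y_true, y_pred)
        assert np.array_equal(report.confusion_matrix,
                              confusion_matrix(y_true, y_pred, labels=[0, 1]))
        p, r, f1, _ = precision_recall_fscore_support(y_true, y_pred,
                                                      labels=[0, 1])
        assert np.allclose(report.precision, p)
        assert np.allclose(report.recall, r)
        assert np.allclose(report.f1, f1)

    def test_f1_between_precision_and_recall(self, rng):
        for _ in range(20):
            y_true = rng.integers(0, 2, size=50)
            y_pred = rng.integers(0, 2, size=50)
            report = f.report_from_predictions(y_true, y_pred)
            for c in range(2):
                if np.isfinite(report.f1[c]):
                    lo = min(report.precision[c], report.recall[c])
                    hi = max(report.precision[c], report.recall[c])
                    assert lo - 1e-12 <= report.f1[c] <= hi + 1e-12

    def test_confusion_sums_to_test_size(self, rng):
        y_true = rng.integers(0, 2, size=77)
        y_pred = rng.integers(0, 2, size=77)
        report = f.report_from_predictions(y_true, y_pred)
        assert report.confusion_matrix.sum() == 77

    def test_absent_class_flagged_undefined_not_zero(self):
        report = f.report_from_predictions([0, 0, 0], [0, 0, 0])
        assert np.isnan(report.recall[1])
        assert "recall_class1" in report.undefined
        assert "macro_f1" in report.undefined
        assert np.isnan(report.macro_f1)

    def test_evaluate_runs_model_and_counts(self, rng):
        model = make_gcn(seed=0)
        X = rng.normal(size=(12, 13, 3))
        y = rng.integers(0, 2, size=12)
        report = f.evaluate(model, X, y)
        preds = model.forward(X).argmax(axis=1)
        oracle = f.report_from_predictions(y, preds)
        assert np.array_equal(report.confusion_matrix, oracle.confusion_matrix)

    def test_report_serializes(self):
        report = f.report_from_predictions([0, 1, 1], [0, 1, 0])
        assert "confusion_matrix" in report.to_json()
        assert "Overall accuracy" in report.to_text()


class TestMacroF1:
    def test_printed_per_class_scores_give_printed_macro(self):
        assert f.macro_f1([81.60, 73.47]) == pytest.approx(77.535)
        assert f.macro_f1([82.53, 69.23]) == pytest.approx(75.88)

    def test_single_class_identity(self):
        assert f.macro_f1([0.42]) == pytest.approx(0.42)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            f.macro_f1([])
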