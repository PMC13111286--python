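"""Focal loss, metrics, cross-validation partitions and the bootstrap."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from qhandpd.autodiff import Tensor
from qhandpd import nn
from qhandpd.network import ModelConfig, build_model
from qhandpd.training import (ArrayDataset, TrainingConfig, bootstrap_ci,
                              evaluate, focal_loss, make_folds,
                              metrics_from_predictions, predict, train)


class TestFocalLoss:
    def test_gamma_zero_equals_cross_entropy(self, rng):
        for _ in range(10):
            p = rng.dirichlet([1, 1], size=6)
            y = rng.integers(0, 2, 6)
            fl = focal_loss(Tensor(p), y, gamma=0.0).item()
            ce = -np.mean(np.log(p[np.arange(6), y]))
            assert abs(fl - ce) < 1e-9

    def test_perfect_prediction_zero_loss(self):
        p = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert focal_loss(Tensor(p), np.array([0, 1]), gamma=3.0).item() \
            == pytest.approx(0.0, abs=1e-6)

    def test_half_confidence_gamma_three(self):
        p = np.array([[0.5, 0.5]])
        val = focal_loss(Tensor(p), np.array([0]), gamma=3.0).item()
        assert val == pytest.approx(0.125 * np.log(2), rel=1e-9)

    def test_strictly_decreasing_in_pt(self):
        pts = np.linspace(0.05, 0.95, 20)
        losses = [focal_loss(Tensor(np.array([[q, 1 - q]])), np.array([0]),
                             gamma=3.0).item() for q in pts]
        assert np.all(np.diff(losses) < 0)
        assert min(losses) >= 0.0

    def test_per_class_alpha(self):
        p = np.array([[0.5, 0.5], [0.5, 0.5]])
        y = np.array([0, 1])
        weighted = focal_loss(Tensor(p), y, gamma=0.0,
                              alpha=np.array([2.0, 0.0])).item()
        assert weighted == pytest.approx(np.log(2))

    def test_negative_gamma_rejected(self):
        with pytest.raises(ValueError):
            focal_loss(Tensor(np.array([[0.5, 0.5]])), np.array([0]),
                       gamma=-1.0)


class TestMetrics:
    def test_printed_confusion_matrix_example(self):
        # TP=10 (class 1), FP=2, FN=3, TN=15
        y_true = np.array([1] * 13 + [0] * 17)
        y_pred = np.array([1] * 10 + [0] * 3 + [0] * 15 + [1] * 2)
        m = metrics_from_predictions(y_true, y_pred)
        prec1, rec1 = 10 / 12, 10 / 13
        prec0, rec0 = 15 / 18, 15 / 17
        assert m.accuracy == pytest.approx(25 / 30)
        assert m.precision == pytest.approx((prec0 + prec1) / 2)
        assert m.recall == pytest.approx((rec0 + rec1) / 2)
        assert m.confusion.tolist() == [[15, 2], [3, 10]]

    def test_all_correct(self):
        y = np.array([0, 1, 0, 1])
        m = metrics_from_predictions(y, y)
        assert (m.accuracy, m.precision, m.recall, m.f1) == (1, 1, 1, 1)

    def test_majority_predictor_on_balanced_data(self):
        y_true = np.array([0, 0, 1, 1])
        m = metrics_from_predictions(y_true, np.zeros(4, dtype=int))
        assert m.accuracy == 0.5


class TestFolds:
    @settings(max_examples=20, deadline=None)
    @given(n=st.integers(10, 60), k=st.integers(2, 5),
           seed=st.integers(0, 100))
    def test_partition_properties(self, n, k, seed):
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, 2, n)
        if labels.sum() < k or (n - labels.sum()) < k:
            labels[:k] = 1
            labels[k:2 * k] = 0
        folds = make_folds(labels, k=k, seed=seed)
        all_val = np.concatenate([va for _, va in folds])
        assert sorted(all_val) == list(range(n))        # union = dataset
        assert len(set(all_val)) == n                   # pairwise disjoint
        for tr, va in folds:
            assert set(tr) | set(va) == set(range(n))
            assert not set(tr) & set(va)

    def test_balanced_fold_sizes(self):
        labels = np.array([0, 1] * 5)
        folds = make_folds(labels, k=5, seed=0)
        assert all(len(va) == 2 for _, va in folds)

    def test_grouping_keeps_patients_together(self):
        labels = np.repeat([0, 1], 20)
        patients = np.repeat(np.arange(10), 4)
        folds = make_folds(labels, k=5, patient_ids=patients, seed=1)
        for _, va in folds:
            val_patients = set(patients[va])
            other = set(patients) - val_patients
            assert not val_patients & other

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            make_folds(np.array([0, 1]), k=5)


class TestBootstrap:
    def test_all_correct_gives_degenerate_interval(self):
        pooled = pd.DataFrame({"true_label": [0, 1, 0, 1],
                               "predicted_label": [0, 1, 0, 1]})
        b = bootstrap_ci(pooled, n_resamples=500, seed=0)
        assert (b.ci_low, b.ci_high, b.width) == (1.0, 1.0, 0.0)
        assert b.mean_accuracy == 1.0

    def test_interval_brackets_observed_accuracy(self, rng):
        correct = rng.random(200) < 0.8
        pooled = pd.DataFrame({"true_label": np.zeros(200, dtype=int),
                               "predicted_label": (~correct).astype(int)})
        b = bootstrap_ci(pooled, n_resamples=2000, seed=1)
        acc = correct.mean()
        assert b.ci_low <= acc <= b.ci_high
        assert b.ci_low <= b.mean_accuracy <= b.ci_high

    def test_four_record_support(self):
        pooled = pd.DataFrame({"true_label": [0, 0, 0, 0],
                               "predicted_label": [0, 0, 0, 1]})
        b = bootstrap_ci(pooled, n_resamples=3000, seed=2)
        correct = (pooled.true_label == pooled.predicted_label).to_numpy()
        rng = np.random.default_rng(2)
        draws = rng.integers(0, 4, size=(3000, 4))
        means = correct[draws].mean(axis=1)
        assert set(np.unique(means)) <= {0.0, 0.25, 0.5, 0.75, 1.0}
        assert 0.0 <= b.ci_low <= b.ci_high <= 1.0

    def test_seed_determinism(self):
        pooled = pd.DataFrame({"true_label": [0, 1, 1, 0, 1],
                               "predicted_label": [0, 1, 0, 0, 1]})
        a = bootstrap_ci(pooled, n_resamples=1000, seed=9)
        b = bootstrap_ci(pooled, n_resamples=1000, seed=9)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)


def _toy_tabular(rng, n=40):
    """Linearly separable tabular-only problem."""
    y = np.repeat([0, 1], n // 2)
    x = rng.uniform(0, np.pi, (n, 6))
    x[:, 2] = np.where(y == 0, rng.uniform(0.1, 0.9, n),
                       rng.uniform(2.2, 3.0, n))
    return ArrayDataset(images=np.zeros((n, 1, 1, 3), np.float32),
                        features=x.astype(np.float32), labels=y,
                        sample_ids=np.arange(n))


class TestTrainLoop:
    def test_separable_toy_reaches_full_training_accuracy(self, rng):
        ds = _toy_tabular(rng)
        model = build_model(ModelConfig(use_image_track=False), seed=0)
        cfg = TrainingConfig(max_epochs=60, lr=0.08, batch_size=16,
                             focal_gamma=0.0, early_stopping_patience=20,
                             seed=0)
        model, history = train(model, ds, ds, cfg)
        assert len(history) <= 60
        assert evaluate(model, ds).accuracy == 1.0

    def test_scheduler_reduces_lr_on_plateau(self):
        opt = nn.Adam([Tensor(np.zeros(2), requires_grad=True)], lr=1e-2)
        sched = nn.ReduceLROnPlateau(opt, factor=0.5, patience=2)
        sched.step(1.0)
        reduced = [sched.step(1.0) for _ in range(4)]
        assert any(reduced)
        assert opt.lr == pytest.approx(5e-3)

    def test_training_is_seed_reproducible(self, rng):
        ds = _toy_tabular(rng, n=24)
        runs = []
        for _ in range(2):
            model = build_model(ModelConfig(use_image_track=False), seed=5)
            cfg = TrainingConfig(max_epochs=3, lr=0.05, seed=5)
            model, history = train(model, ds, ds, cfg)
            runs.append((history[-1]["val_loss"],
                         predict(model, ds)["p_pd"].to_numpy()))
        assert runs[0][0] == runs[1][0]
        assert np.array_equal(runs[0][1], runs[1][1])

    def test_empty_sets_rejected(self, rng):
        ds = _toy_tabular(rng, n=8)
        with pytest.raises(ValueError):
            train(build_model(ModelConfig(use_image_track=False), seed=0),
                  ds.subset(np.array([], dtype=int)), ds, TrainingConfig())
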