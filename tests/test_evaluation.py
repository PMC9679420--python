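"""Bookkeeping, splits, metrics and the training loop."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bspmaf.errors import InvalidParameterError, ShapeError, UndefinedMetricError
from bspmaf.evaluation import (
    TrainConfig,
    confusion_metrics,
    count_segments_by_outcome,
    inter_patient_folds,
    intra_patient_split,
    load_subject_table,
    plan_from_patient_folds,
    roc_auc,
    train_model,
)
from bspmaf.model import NetworkConfig, build_network, predict


class TestSubjectTable:
    def test_bundled_inventory_segment_totals(self):
        non, rec = count_segments_by_outcome(load_subject_table())
        assert rec == 359
        assert non == 813

    def test_bundled_inventory_shape(self):
        table = load_subject_table()
        assert len(table) == 14
        assert (table["recurrence"] == "Yes").sum() == 4

    def test_empty_table_counts_zero(self):
        empty = pd.DataFrame(columns=["id", "recurrence", "segments"])
        assert count_segments_by_outcome(empty) == (0, 0)


class TestIntraSplit:
    def test_hundred_segments_split_70_20_10(self):
        plan = intra_patient_split(100, seed=0)
        assert (len(plan.train_idx), len(plan.val_idx), len(plan.test_idx)) == (70, 20, 10)

    def test_partition_is_disjoint_and_exhaustive(self):
        plan = intra_patient_split(57, seed=3)
        union = np.concatenate([plan.train_idx, plan.val_idx, plan.test_idx])
        assert sorted(union) == list(range(57))

    def test_seeded_determinism(self):
        p1, p2 = intra_patient_split(40, seed=9), intra_patient_split(40, seed=9)
        np.testing.assert_array_equal(p1.train_idx, p2.train_idx)
        np.testing.assert_array_equal(p1.test_idx, p2.test_idx)

    def test_bad_ratios_rejected(self):
        with pytest.raises(InvalidParameterError):
            intra_patient_split(100, ratios=(7, 0, 1))


class TestInterFolds:
    ids = [f"P{i:02d}" for i in range(14)]
    labels = [i < 4 for i in range(14)]  # 4 recurrent patients

    def test_fold_sizes_balanced(self):
        folds = inter_patient_folds(self.ids, self.labels, seed=0)
        sizes = sorted(len(test) for _, test in folds)
        assert sizes == [2, 3, 3, 3, 3]

    def test_test_and_train_patients_disjoint(self):
        for train, test in inter_patient_folds(self.ids, self.labels, seed=1):
            assert not set(train) & set(test)
            assert set(train) | set(test) == set(self.ids)

    def test_recurrent_patients_spread_and_training_never_empty_of_them(self):
        folds = inter_patient_folds(self.ids, self.labels, seed=2)
        recurrent = set(self.ids[:4])
        for train, test in folds:
            assert len(recurrent & set(test)) <= 1
            assert len(recurrent & set(train)) >= 1

    def test_fewer_patients_than_folds_rejected(self):
        with pytest.raises(InvalidParameterError):
            inter_patient_folds(["a", "b"], [True, False], n_folds=5)

    def test_plan_maps_segments_by_patient(self):
        seg_patients = ["P00"] * 3 + ["P01"] * 3 + ["P02"] * 3
        fold = (("P00", "P01"), ("P02",))
        plan = plan_from_patient_folds(seg_patients, fold, seed=0)
        assert sorted(plan.test_idx) == [6, 7, 8]
        assert sorted(np.concatenate([plan.train_idx, plan.val_idx])) == list(range(6))


class TestConfusionMetrics:
    def test_perfect_classifier(self):
        rep = confusion_metrics(np.array([1.0] * 5 + [0.0] * 5), np.array([1] * 5 + [0] * 5))
        assert (rep.SE, rep.SP, rep.PPV, rep.ACC) == (100.0, 100.0, 100.0, 100.0)

    def test_degenerate_denominator_gives_nan_with_warning(self):
        with pytest.warns(RuntimeWarning):
            rep = confusion_metrics(np.array([1, 0, 1, 0.0]), np.array([1, 1, 1, 1]))
        assert rep.SE == 50.0
        assert np.isnan(rep.SP)

    def test_worked_example(self):
        # TP=3, TN=4, FP=1, FN=2
        scores = np.array([1, 1, 1, 0, 0, 0, 0, 0, 1, 0.0])
        labels = np.array([1, 1, 1, 1, 1, 0, 0, 0, 0, 0])
        rep = confusion_metrics(scores, labels)
        assert (rep.TP, rep.TN, rep.FP, rep.FN) == (3, 4, 1, 2)
        assert rep.SE == pytest.approx(60.0)
        assert rep.SP == pytest.approx(80.0)
        assert rep.PPV == pytest.approx(75.0)
        assert rep.ACC == pytest.approx(70.0)

    def test_length_mismatch_raises(self):
        with pytest.raises(ShapeError):
            confusion_metrics(np.zeros(3), np.zeros(4))

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.tuples(st.booleans(), st.booleans()), min_size=1, max_size=40))
    def test_matches_exhaustive_counting(self, pairs):
        pred = np.array([p for p, _ in pairs], dtype=float)
        lab = np.array([int(l) for _, l in pairs])
        rep = confusion_metrics(pred, lab)
        tp = sum(1 for p, l in pairs if p and l)
        tn = sum(1 for p, l in pairs if not p and not l)
        fp = sum(1 for p, l in pairs if p and not l)
        fn = sum(1 for p, l in pairs if not p and l)
        assert (rep.TP, rep.TN, rep.FP, rep.FN) == (tp, tn, fp, fn)
        assert rep.ACC == pytest.approx(100.0 * (tp + tn) / len(pairs))


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_worked_example_by_pair_counting(self):
        assert roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)

    def test_random_scores_near_half(self, rng):
        scores = rng.uniform(size=2000)
        labels = rng.integers(0, 2, size=2000)
        assert roc_auc(scores, labels) == pytest.approx(0.5, abs=0.05)

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedMetricError):
            roc_auc([0.1, 0.9], [1, 1])

    @settings(max_examples=40, deadline=None)
    @given(st.integers(0, 5000))
    def test_matches_exhaustive_pair_counting(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 30))
        scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n)
        labels = rng.integers(0, 2, size=n)
        if len(np.unique(labels)) < 2:
            return
        wins = ties = 0
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        for p in pos:
            for q in neg:
                wins += p > q
                ties += p == q
        expected = (wins + 0.5 * ties) / (len(pos) * len(neg))
        assert roc_auc(scores, labels) == pytest.approx(expected, abs=1e-12)


@pytest.fixture(scope="module")
def toy_data():
    rng = np.random.default_rng(0)
    x = rng.uniform(0.4, 0.6, size=(24, 16, 16, 16))
    y = np.arange(24) % 2
    x[y == 1, :, 8:, :] += 0.3
    return x, y


class TestTrainingLoop:
    def small_net(self, seed=0):
        cfg = NetworkConfig(input_hwt=(16, 16, 16), base_channels=2,
                            dense_dim=32, dense_hidden=8)
        return build_network(cfg, seed=seed)

    def test_two_epoch_history_and_loss_decrease(self, toy_data):
        x, y = toy_data
        model, hist = train_model(self.small_net(), x[:16], y[:16], x[16:], y[16:],
                                  TrainConfig(epochs=2, batch_size=8, seed=0))
        assert len(hist.train_loss) == 2
        assert len(hist.val_acc) == 2

    def test_deterministic_training(self, toy_data):
        x, y = toy_data
        m1, h1 = train_model(self.small_net(seed=5), x[:16], y[:16], x[16:], y[16:],
                             TrainConfig(epochs=2, batch_size=8, seed=3))
        m2, h2 = train_model(self.small_net(seed=5), x[:16], y[:16], x[16:], y[16:],
                             TrainConfig(epochs=2, batch_size=8, seed=3))
        assert h1.train_loss == h2.train_loss
        for a, b in zip(m1.parameters(), m2.parameters()):
            np.testing.assert_array_equal(a.data, b.data)

    def test_best_checkpoint_at_least_as_good_as_last_epoch(self, toy_data):
        x, y = toy_data
        model, hist = train_model(self.small_net(), x[:16], y[:16], x[16:], y[16:],
                                  TrainConfig(epochs=4, batch_size=8, seed=1))
        assert hist.best_val_acc >= hist.val_acc[-1]
        probs = predict(model, x[16:])[:, 1]
        acc = 100.0 * np.mean((probs >= 0.5).astype(int) == y[16:])
        assert acc == pytest.approx(hist.best_val_acc, abs=1e-9)
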