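"""Fold construction, class weighting, metrics, and the training loop."""

import math

import numpy as np
import pytest

from afibnet.metrics import ClassCounts, compute_metrics, fold_average, report_frame
from afibnet.model import ModelConfig, build_model
from afibnet.train import (
    TrainConfig,
    class_weights,
    evaluate,
    make_folds,
    run_protocol,
    train_fold,
)


def brute_force_counts(y_true, y_pred, cls):
    """Independent recount of the one-vs-rest confusion entries."""
    tp = sum(t == cls and p == cls for t, p in zip(y_true, y_pred))
    fp = sum(t != cls and p == cls for t, p in zip(y_true, y_pred))
    fn = sum(t == cls and p != cls for t, p in zip(y_true, y_pred))
    tn = len(y_true) - tp - fp - fn
    return tp, fp, fn, tn


class TestMetrics:
    def test_hand_evaluated_binary_case(self):
        # TP=90, FN=10, TN=95, FP=5 for the AF class.
        y_true = ["AF"] * 100 + ["N"] * 100
        y_pred = ["AF"] * 90 + ["N"] * 10 + ["N"] * 95 + ["AF"] * 5
        rep = compute_metrics(y_true, y_pred, ("N", "AF"))
        s = rep.summary()
        assert s["sensitivity"] == pytest.approx(0.90)
        assert s["specificity"] == pytest.approx(0.95)
        assert s["accuracy"] == pytest.approx(0.925)
        assert s["precision"] == pytest.approx(90 / 95)  # ~94.74%

    def test_perfect_predictions_give_unity_everywhere(self):
        y = ["N", "AF", "AF", "N", "AF"]
        s = compute_metrics(y, y, ("N", "AF")).summary()
        assert all(v == pytest.approx(1.0) for v in s.values())

    def test_degenerate_single_class_prediction(self):
        y_true = ["N", "N", "AF", "AF"]
        y_pred = ["N", "N", "N", "N"]
        rep = compute_metrics(y_true, y_pred, ("N", "AF"))
        assert rep.counts["N"].sensitivity == 1.0
        assert rep.counts["AF"].sensitivity == 0.0
        assert math.isnan(rep.counts["AF"].precision)  # 0/0, reported as NaN

    def test_agrees_with_brute_force_recount(self, rng):
        classes = ("N", "AF", "NON_AF")
        y_true = rng.choice(classes, size=300).tolist()
        y_pred = rng.choice(classes, size=300).tolist()
        rep = compute_metrics(y_true, y_pred, classes)
        for c in classes:
            cc = rep.counts[c]
            assert (cc.tp, cc.fp, cc.fn, cc.tn) == brute_force_counts(y_true, y_pred, c)

    def test_binary_accuracy_identity(self, rng):
        """accuracy == (sens * P + spec * N) / (P + N) on binary data."""
        for _ in range(10):
            y_true = rng.choice(["N", "AF"], size=80).tolist()
            y_pred = rng.choice(["N", "AF"], size=80).tolist()
            if len(set(y_true)) < 2:
                continue
            rep = compute_metrics(y_true, y_pred, ("N", "AF"))
            s = rep.summary()
            P = y_true.count("AF")
            Nn = y_true.count("N")
            assert s["accuracy"] == pytest.approx(
                (s["sensitivity"] * P + s["specificity"] * Nn) / (P + Nn))

    def test_fold_average_is_arithmetic_mean(self):
        s1 = dict(accuracy=1.0, sensitivity=1.0, specificity=0.8, f1=0.9, precision=0.9)
        s2 = dict(accuracy=0.5, sensitivity=0.7, specificity=1.0, f1=0.7, precision=0.8)
        avg = fold_average([s1, s2])
        assert avg["accuracy"] == pytest.approx(0.75)
        assert avg["specificity"] == pytest.approx(0.9)

    def test_report_frame_layout(self):
        s = dict(accuracy=0.998, sensitivity=0.998, specificity=0.998, f1=0.9977, precision=0.9974)
        frame = report_frame([s] * 3, fold_average([s] * 3))
        assert list(frame["fold"]) == ["1", "2", "3", "Average"]
        assert frame.loc[3, "accuracy"] == 99.8

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics([], [], ("N", "AF"))


class TestClassWeights:
    def test_inverse_frequency_formula(self):
        labels = ["N"] * 80 + ["AF"] * 20
        w = class_weights(labels, ("N", "AF"))
        assert w["N"] == pytest.approx(100 / (2 * 80))  # 0.625
        assert w["AF"] == pytest.approx(100 / (2 * 20))  # 2.5

    def test_absent_class_rejected(self):
        with pytest.raises(ValueError, match="AF"):
            class_weights(["N"] * 5, ("N", "AF"))


class TestMakeFolds:
    def test_single_episode_subjects_partition(self):
        labels = ["N"] * 50 + ["AF"] * 50
        subjects = [f"s{i}" for i in range(100)]
        plan = make_folds(labels, subjects, k=10, split_mode="inter_patient", seed=0)
        all_val = np.concatenate([f["val"] for f in plan.folds])
        assert sorted(all_val.tolist()) == list(range(100))
        for f in plan.folds:
            assert len(f["train"]) == 90 and len(f["val"]) == 10

    def test_inter_patient_no_subject_overlap(self):
        labels = (["N"] * 5 + ["AF"] * 5) * 20
        subjects = [f"s{i % 20}" for i in range(200)]
        plan = make_folds(labels, subjects, k=10, split_mode="inter_patient", seed=3)
        for f in plan.folds:
            tr = {subjects[i] for i in f["train"]}
            va = {subjects[i] for i in f["val"]}
            assert not (tr & va)

    def test_too_few_subjects_rejected_with_counts(self):
        with pytest.raises(ValueError, match="5"):
            make_folds(["N"] * 10, ["s1", "s2", "s3", "s4", "s5"] * 2,
                       k=10, split_mode="inter_patient")

    def test_deterministic_given_seed(self):
        labels = ["N"] * 60 + ["AF"] * 40
        subjects = [f"s{i % 25}" for i in range(100)]
        p1 = make_folds(labels, subjects, k=10, seed=5)
        p2 = make_folds(labels, subjects, k=10, seed=5)
        for f1, f2 in zip(p1.folds, p2.folds):
            np.testing.assert_array_equal(f1["train"], f2["train"])
            np.testing.assert_array_equal(f1["val"], f2["val"])
            assert f1["class_weights"] == f2["class_weights"]

    def test_intra_patient_stratified(self):
        labels = ["N"] * 80 + ["AF"] * 20
        subjects = ["s0"] * 100
        plan = make_folds(labels, subjects, k=10, split_mode="intra_patient", seed=1)
        for f in plan.folds:
            val_labels = [labels[i] for i in f["val"]]
            assert val_labels.count("N") == 8 and val_labels.count("AF") == 2


def _tiny_dataset(rng, n=60):
    """Small separable episode set: two amplitude-coded classes."""
    x = rng.normal(0, 0.1, size=(n, 2700))
    labels = []
    for i in range(n):
        if i % 2 == 0:
            x[i, ::100] += 3.0
            labels.append("N")
        else:
            x[i, ::37] -= 3.0
            labels.append("AF")
    subjects = [f"s{i % 12}" for i in range(n)]
    return x, labels, subjects


class TestTrainFold:
    def test_loss_decreases(self, rng):
        x, labels, _ = _tiny_dataset(rng)
        model = build_model(ModelConfig.scaled(2), seed=0)
        _, log = train_fold(model, x, labels, np.arange(len(labels)),
                            TrainConfig(epochs=3, seed=0))
        assert log[-1] < log[0]

    def test_zero_learning_rate_is_identity(self, rng):
        x, labels, _ = _tiny_dataset(rng, n=20)
        model = build_model(ModelConfig.scaled(2), seed=1)
        before = [p.copy() for p in model.network.params]
        # batch size divides n so the epoch-mean loss is shuffle-invariant
        _, log = train_fold(model, x, labels, np.arange(20),
                            TrainConfig(learning_rate=0.0, batch_size=10, epochs=2, seed=0))
        for b, a in zip(before, model.network.params):
            np.testing.assert_array_equal(b, a)
        assert log[0] == pytest.approx(log[1])

    def test_missing_class_rejected_before_training(self, rng):
        x, labels, _ = _tiny_dataset(rng, n=20)
        model = build_model(ModelConfig.scaled(2), seed=0)
        only_n = [i for i, l in enumerate(labels) if l == "N"]
        with pytest.raises(ValueError, match="absent"):
            train_fold(model, x, labels, np.array(only_n), TrainConfig(epochs=1))

    def test_evaluate_empty_rejected(self):
        model = build_model(ModelConfig.scaled(2), seed=0)
        with pytest.raises(ValueError):
            evaluate(model, np.empty((0, 2700)), [])


class TestRunProtocol:
    @pytest.fixture(scope="class")
    def dataset(self):
        rng = np.random.default_rng(77)
        return _tiny_dataset(rng, n=60)

    def test_structure_and_determinism(self, dataset, tmp_path):
        x, labels, subjects = dataset
        cfg = TrainConfig(epochs=1, k=4, seed=2)
        r1 = run_protocol(x, labels, subjects, ModelConfig.scaled(2), cfg,
                          split_mode="intra_patient", out_dir=tmp_path / "run1")
        r2 = run_protocol(x, labels, subjects, ModelConfig.scaled(2), cfg,
                          split_mode="intra_patient", out_dir=tmp_path / "run2")
        assert len(r1.summaries) == 4
        assert r1.average == r2.average
        assert (tmp_path / "run1" / "metrics.csv").read_bytes() == \
               (tmp_path / "run2" / "metrics.csv").read_bytes()
        assert (tmp_path / "run1" / "report.json").read_bytes() == \
               (tmp_path / "run2" / "report.json").read_bytes()

    def test_metrics_table_has_fold_rows_plus_average(self, dataset, tmp_path):
        import pandas as pd

        x, labels, subjects = dataset
        run_protocol(x, labels, subjects, ModelConfig.scaled(2),
                     TrainConfig(epochs=1, k=4, seed=0),
                     split_mode="intra_patient", out_dir=tmp_path)
        frame = pd.read_csv(tmp_path / "metrics.csv")
        assert len(frame) == 5 and frame["fold"].iloc[-1] == "Average"

    def test_three_class_report_covers_all_classes(self, rng):
        x = rng.normal(0, 0.1, size=(45, 2700))
        labels = (["N", "AF", "NON_AF"] * 15)
        for i, l in enumerate(labels):
            shift = {"N": 0, "AF": 1, "NON_AF": 2}[l]
            x[i, shift::50] += 3.0
        subjects = [f"s{i % 9}" for i in range(45)]
        res = run_protocol(x, labels, subjects, ModelConfig.scaled(3),
                           TrainConfig(epochs=1, k=3, seed=0),
                           split_mode="intra_patient")
        assert set(res.reports[0].counts) == {"N", "AF", "NON_AF"}
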