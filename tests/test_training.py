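import numpy as np
import pytest

from hrvnet.training import (
    ConfusionCounts,
    ReduceLROnPlateau,
    TrainConfig,
    compute_metrics,
    confusion_counts,
    lr_schedule_step,
    roc_auc,
    run_cross_validation,
    subject_wise_kfold,
    train_fold,
)


def pairwise_auc(labels, scores):
    """Brute-force AUC: P(random positive outscores random negative), ties ½."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestKFold:
    def test_even_split_of_twenty_subjects(self):
        split = subject_wise_kfold([f"s{i}" for i in range(20)], k=10, seed=0)
        assert all(len(p) == 2 for p in split.parts)
        union = set().union(*split.parts)
        assert len(union) == 20

    def test_part_sizes_for_83_subjects(self):
        split = subject_wise_kfold([f"s{i}" for i in range(83)], k=10, seed=1)
        sizes = sorted(len(p) for p in split.parts)
        assert sizes == [8] * 7 + [9] * 3

    def test_each_subject_in_exactly_one_part(self):
        ids = [f"s{i}" for i in range(37)]
        split = subject_wise_kfold(ids, k=5, seed=3)
        seen = [s for p in split.parts for s in p]
        assert sorted(seen) == sorted(ids)

    def test_folds_are_leakage_free(self):
        ids = [f"s{i}" for i in range(25)]
        split = subject_wise_kfold(ids, k=5, seed=2)
        for fold in split.folds:
            assert not (fold.train | fold.val) & fold.test
            assert not fold.train & fold.val
            assert fold.train | fold.val | fold.test == set(ids)

    def test_stratified_parts_balance_classes(self):
        ids = [f"n{i}" for i in range(10)] + [f"c{i}" for i in range(10)]
        labels = {s: (0 if s.startswith("n") else 1) for s in ids}
        split = subject_wise_kfold(ids, k=2, seed=0, labels=labels)
        for part in split.parts:
            counts = [sum(1 for s in part if labels[s] == c) for c in (0, 1)]
            assert counts == [5, 5]

    def test_validation_set_covers_both_classes(self):
        ids = [f"n{i}" for i in range(6)] + [f"c{i}" for i in range(6)]
        labels = {s: (0 if s.startswith("n") else 1) for s in ids}
        split = subject_wise_kfold(ids, k=3, seed=1, labels=labels)
        for fold in split.folds:
            assert {labels[s] for s in fold.val} == {0, 1}

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            subject_wise_kfold(["a", "b"], k=3)


class TestScheduler:
    def test_five_stale_epochs_cut_rate_tenfold(self):
        cfg = TrainConfig()
        history = [0.5] + [0.5] * 5
        assert lr_schedule_step(history, 1e-4, cfg) == pytest.approx(1e-5)

    def test_improving_history_keeps_rate(self):
        cfg = TrainConfig()
        history = [0.5, 0.4, 0.3, 0.2, 0.1, 0.05]
        assert lr_schedule_step(history, 1e-4, cfg) == pytest.approx(1e-4)

    def test_two_plateaus_cut_twice(self):
        cfg = TrainConfig()
        history = [0.5] + [0.5] * 5 + [0.4] + [0.4] * 5
        assert lr_schedule_step(history, 1e-4, cfg) == pytest.approx(1e-6)

    def test_rate_is_nonincreasing(self):
        sched = ReduceLROnPlateau(1e-4)
        rng = np.random.default_rng(0)
        last = 1e-4
        for loss in rng.random(50):
            lr = sched.step(float(loss))
            assert lr <= last
            last = lr

    def test_empty_history_rejected(self):
        with pytest.raises(ValueError):
            lr_schedule_step([], 1e-4, TrainConfig())


class TestConfusionAndMetrics:
    def test_hand_counted_example(self):
        cc = confusion_counts([1, 1, 0, 0], [0.9, 0.2, 0.1, 0.8])
        assert (cc.tp, cc.fn, cc.tn, cc.fp) == (1, 1, 1, 1)

    def test_perfect_classifier(self):
        cc = confusion_counts([1, 0, 1], [0.9, 0.1, 0.8])
        assert cc.fp == 0 and cc.fn == 0

    def test_threshold_ties_classified_positive(self):
        cc = confusion_counts([1, 0], [0.5, 0.5])
        assert cc.tp == 1 and cc.fp == 1

    def test_counts_partition_the_sample(self, rng):
        for _ in range(50):
            n = int(rng.integers(1, 40))
            y = rng.integers(0, 2, n)
            p = rng.random(n)
            assert confusion_counts(y, p).n == n

    def test_metric_formulas_by_hand(self):
        m = compute_metrics(ConfusionCounts(tp=3, fp=1, tn=4, fn=2))
        assert m["accuracy"] == pytest.approx(0.7)
        assert m["recall"] == pytest.approx(0.6)
        assert m["precision"] == pytest.approx(0.75)
        assert m["f1"] == pytest.approx(2 / 3, abs=1e-4)

    def test_degenerate_counts_yield_zero(self):
        m = compute_metrics(ConfusionCounts(tp=0, fp=0, tn=5, fn=3))
        assert m["recall"] == 0.0 and m["precision"] == 0.0 and m["f1"] == 0.0

    def test_metric_identities_on_random_tables(self, rng):
        for _ in range(200):
            tp, fp, tn, fn = (int(v) for v in rng.integers(0, 30, 4))
            if tp + fp + tn + fn == 0:
                continue
            m = compute_metrics(ConfusionCounts(tp, fp, tn, fn))
            assert m["accuracy"] == pytest.approx((tp + tn) / (tp + fp + tn + fn))
            if m["precision"] + m["recall"] > 0:
                expected_f1 = (2 * m["precision"] * m["recall"]
                               / (m["precision"] + m["recall"]))
                assert m["f1"] == pytest.approx(expected_f1)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            confusion_counts([], [])
        with pytest.raises(ValueError):
            compute_metrics(ConfusionCounts(0, 0, 0, 0))


class TestROCAUC:
    def test_perfect_separation(self):
        _, _, auc = roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert auc == 1.0

    def test_uninformative_scores_near_half(self, rng):
        n = 10000
        y = rng.integers(0, 2, n)
        p = rng.random(n)
        _, _, auc = roc_auc(y, p)
        assert auc == pytest.approx(0.5, abs=0.02)

    def test_matches_pairwise_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 50))
            y = rng.integers(0, 2, n)
            if len(set(y.tolist())) < 2:
                continue
            p = np.round(rng.random(n), 2)  # rounding forces ties
            _, _, auc = roc_auc(y, p)
            assert auc == pytest.approx(pairwise_auc(y, p), abs=1e-10)

    def test_roc_runs_from_origin_to_one_one(self, rng):
        y = rng.integers(0, 2, 50)
        y[:2] = [0, 1]
        p = rng.random(50)
        fpr, tpr, _ = roc_auc(y, p)
        assert fpr[0] == 0 and tpr[0] == 0
        assert fpr[-1] == 1 and tpr[-1] == 1
        assert np.all(np.diff(fpr) >= 0) and np.all(np.diff(tpr) >= 0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 1], [0.5, 0.6])


class TestTrainFold:
    def test_zero_epochs_returns_initialized_model(
        self, tiny_cohort_segments, tiny_net_cfg
    ):
        cfg = TrainConfig(epochs=0, seed=1)
        model, curves = train_fold(tiny_cohort_segments, [], tiny_net_cfg, cfg)
        assert curves["train_loss"] == []
        x = np.stack([s.padded_values for s in tiny_cohort_segments[:2]])
        assert np.allclose(model.predict(x), 0.5)  # zero-init head

    def test_same_seed_reproduces_training(
        self, tiny_cohort_segments, tiny_net_cfg, fast_train_cfg
    ):
        _, c1 = train_fold(tiny_cohort_segments, [], tiny_net_cfg, fast_train_cfg)
        _, c2 = train_fold(tiny_cohort_segments, [], tiny_net_cfg, fast_train_cfg)
        assert c1["train_loss"] == c2["train_loss"]

    def test_single_class_training_set_rejected(
        self, tiny_cohort_segments, tiny_net_cfg
    ):
        chf_only = [s for s in tiny_cohort_segments if s.label == 1]
        with pytest.raises(ValueError, match="both classes"):
            train_fold(chf_only, [], tiny_net_cfg, TrainConfig(epochs=1))

    def test_learns_separable_classes(self, tiny_cohort_segments, tiny_net_cfg):
        cfg = TrainConfig(batch_size=8, epochs=10, initial_lr=1e-2, seed=0)
        model, curves = train_fold(tiny_cohort_segments, [], tiny_net_cfg, cfg)
        assert curves["train_acc"][-1] >= 0.95


class TestCrossValidation:
    def test_report_complete_and_leakage_free(
        self, tiny_cohort_segments, tiny_net_cfg, fast_train_cfg
    ):
        report = run_cross_validation(
            tiny_cohort_segments, tiny_net_cfg, fast_train_cfg, k=2
        )
        assert len(report.folds) == 2
        tested = [f.test_subjects for f in report.folds]
        assert not tested[0] & tested[1]
        total = report.pooled_confusion
        summed = report.folds[0].confusion + report.folds[1].confusion
        assert (total.tp, total.fp, total.tn, total.fn) == (
            summed.tp, summed.fp, summed.tn, summed.fn,
        )
        assert total.n == len(tiny_cohort_segments)
        assert set(report.pooled_metrics) == {
            "accuracy", "recall", "precision", "f1",
        }

    def test_single_class_cohort_rejected(self, tiny_cohort_segments):
        nsr_only = [s for s in tiny_cohort_segments if s.label == 0]
        with pytest.raises(ValueError):
            run_cross_validation(nsr_only, None, TrainConfig(epochs=1), k=2)
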