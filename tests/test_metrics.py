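"""Tests for the hard-label multi-class evaluation stack."""

import numpy as np
import pytest
import sklearn.metrics as skm

from emdimage import (
    ClassCounts,
    PredictionSet,
    aggregate_report,
    basic_metrics,
    bootstrap_ci,
    class_counts,
    confusion_matrix,
    cross_entropy,
    make_prediction_fixture,
    onehot_roc_auc,
)

from _reference import brute_force_confusion, hand_cross_entropy


def accuracy_metric(p: PredictionSet) -> float:
    return float(np.mean(p.true_labels == p.predicted_labels))


@pytest.fixture(scope="module")
def random_fixtures():
    """20 seeded prediction sets with heterogeneous per-class rates."""
    out = []
    for seed in range(20):
        rng = np.random.default_rng(seed)
        tpr = rng.uniform(0.3, 1.0, size=8)
        y_true, y_pred = make_prediction_fixture(tpr, n=600, seed=seed)
        out.append(PredictionSet(y_true, y_pred, n_classes=8))
    return out


class TestConfusionMatrix:
    def test_perfect_predictions_are_diagonal(self):
        y = np.repeat(np.arange(8), 10)
        conf = confusion_matrix(PredictionSet(y, y))
        np.testing.assert_array_equal(conf, np.eye(8, dtype=int) * 10)

    def test_all_predicted_one_class_fills_single_column(self):
        y = np.repeat(np.arange(4), 5)
        conf = confusion_matrix(PredictionSet(y, np.zeros_like(y), n_classes=4))
        assert conf[:, 0].sum() == 20
        assert conf[:, 1:].sum() == 0

    def test_matches_brute_force_tally(self, random_fixtures):
        for preds in random_fixtures:
            np.testing.assert_array_equal(
                confusion_matrix(preds),
                brute_force_confusion(preds.true_labels, preds.predicted_labels, 8),
            )

    def test_marginals_conserved(self, random_fixtures):
        preds = random_fixtures[0]
        conf = confusion_matrix(preds)
        assert conf.sum() == len(preds)
        np.testing.assert_array_equal(conf.sum(axis=1), np.bincount(preds.true_labels, minlength=8))
        np.testing.assert_array_equal(conf.sum(axis=0), np.bincount(preds.predicted_labels, minlength=8))

    def test_label_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="range"):
            PredictionSet([0, 1], [0, 3], n_classes=2)


class TestClassCounts:
    def test_diagonal_matrix_has_no_errors(self):
        conf = np.eye(8, dtype=int) * 5
        for c in range(8):
            cc = class_counts(conf, c)
            assert cc.fp == 0 and cc.fn == 0

    def test_binary_marginalization_example(self):
        cc = class_counts(np.array([[40, 20], [10, 30]]), 0)
        assert (cc.tp, cc.fn, cc.fp, cc.tn) == (40, 20, 10, 30)

    def test_counts_total_n_for_every_class(self, random_fixtures):
        preds = random_fixtures[1]
        conf = confusion_matrix(preds)
        for c in range(8):
            assert class_counts(conf, c).n == len(preds)


class TestBasicMetrics:
    def test_worked_example(self):
        m = basic_metrics(ClassCounts(tp=40, tn=30, fp=10, fn=20))
        assert m["precision"] == pytest.approx(0.8, abs=1e-12)
        assert m["recall"] == pytest.approx(2 / 3, abs=1e-12)
        assert m["f1"] == pytest.approx(8 / 11, abs=1e-12)
        assert m["accuracy"] == pytest.approx(0.7, abs=1e-12)

    def test_all_correct_positives_give_ones(self):
        m = basic_metrics(ClassCounts(tp=50, tn=0, fp=0, fn=0))
        assert all(v == 1.0 for v in m.values())

    def test_zero_over_zero_is_zero(self):
        m = basic_metrics(ClassCounts(tp=0, tn=90, fp=0, fn=10))
        assert m["precision"] == 0.0
        assert m["f1"] == 0.0


class TestOnehotROCAUC:
    def test_perfect_predictions_auc_one(self):
        y = np.repeat(np.arange(8), 5)
        _, auc = onehot_roc_auc(PredictionSet(y, y), 0)
        assert auc == 1.0

    def test_auc_is_balanced_accuracy(self):
        # TPR 0.9, FPR 0.2 by construction
        y_true = np.array([1] * 100 + [0] * 100)
        y_pred = np.concatenate([np.repeat([1, 0], [90, 10]), np.repeat([1, 0], [20, 80])])
        roc, auc = onehot_roc_auc(PredictionSet(y_true, y_pred), 1)
        assert auc == pytest.approx(0.85, abs=1e-12)
        np.testing.assert_allclose(roc[1], [0.2, 0.9])

    def test_complement_predictions_auc_zero(self):
        y = np.array([0, 1] * 20)
        _, auc = onehot_roc_auc(PredictionSet(y, 1 - y), 1)
        assert auc == 0.0

    def test_absent_class_flagged_nan(self):
        preds = PredictionSet([0, 0, 1], [0, 1, 1], n_classes=3)
        _, auc = onehot_roc_auc(preds, 2)
        assert np.isnan(auc)

    def test_identity_with_tpr_tnr_mean(self, random_fixtures):
        for preds in random_fixtures[:5]:
            conf = confusion_matrix(preds)
            for c in range(8):
                cc = class_counts(conf, c)
                if cc.tp + cc.fn == 0:
                    continue
                tpr = cc.tp / (cc.tp + cc.fn)
                tnr = cc.tn / (cc.tn + cc.fp)
                _, auc = onehot_roc_auc(preds, c)
                assert auc == pytest.approx((tpr + tnr) / 2, abs=1e-12)


class TestAggregateReport:
    def test_perfect_eight_class_report(self):
        y = np.repeat(np.arange(8), 5)
        rep = aggregate_report(PredictionSet(y, y))
        assert rep.accuracy == 1.0
        assert rep.macro_f1 == 1.0
        assert rep.mean_auc == 1.0

    def test_uniform_random_predictions_near_chance(self):
        rng = np.random.default_rng(0)
        y_true = np.repeat(np.arange(8), 1000)
        y_pred = rng.integers(0, 8, size=8000)
        rep = aggregate_report(PredictionSet(y_true, y_pred))
        assert 0.115 <= rep.accuracy <= 0.135

    def test_macro_f1_is_mean_of_per_class(self, random_fixtures):
        rep = aggregate_report(random_fixtures[2])
        assert rep.macro_f1 == pytest.approx(rep.per_class["f1"].mean(), abs=1e-15)

    def test_equivalence_with_sklearn(self, random_fixtures):
        for preds in random_fixtures:
            rep = aggregate_report(preds)
            p, r, f, _ = skm.precision_recall_fscore_support(
                preds.true_labels, preds.predicted_labels, labels=range(8), zero_division=0
            )
            np.testing.assert_allclose(rep.per_class["precision"], p, atol=1e-12)
            np.testing.assert_allclose(rep.per_class["recall"], r, atol=1e-12)
            np.testing.assert_allclose(rep.per_class["f1"], f, atol=1e-12)
            np.testing.assert_allclose(
                rep.confusion,
                skm.confusion_matrix(preds.true_labels, preds.predicted_labels, labels=range(8)),
            )
            assert rep.accuracy == pytest.approx(
                skm.accuracy_score(preds.true_labels, preds.predicted_labels), abs=1e-12
            )


class TestCrossEntropy:
    def test_certain_correct_prediction_is_zero(self):
        probs = np.zeros((4, 8))
        probs[np.arange(4), [0, 1, 2, 3]] = 1.0
        preds = PredictionSet([0, 1, 2, 3], [0, 1, 2, 3], probs, n_classes=8)
        assert cross_entropy(preds) == 0.0

    def test_uniform_over_eight_classes_is_ln8(self):
        probs = np.full((10, 8), 1 / 8)
        preds = PredictionSet(np.arange(10) % 8, np.arange(10) % 8, probs)
        assert cross_entropy(preds) == pytest.approx(np.log(8), abs=1e-12)

    def test_matches_hand_summed_oracle_and_sklearn(self):
        rng = np.random.default_rng(3)
        probs = rng.dirichlet(np.ones(8), size=50)
        y = rng.integers(0, 8, size=50)
        preds = PredictionSet(y, probs.argmax(axis=1), probs)
        ours = cross_entropy(preds)
        assert ours == pytest.approx(hand_cross_entropy(y, probs), abs=1e-12)
        assert ours == pytest.approx(skm.log_loss(y, probs, labels=range(8)), abs=1e-9)

    def test_requires_probabilities(self):
        with pytest.raises(ValueError, match="probabilities"):
            cross_entropy(PredictionSet([0, 1], [0, 1], n_classes=2))


class TestBootstrapCI:
    def test_constant_metric_gives_zero_width_at_one(self):
        y = np.zeros(100, dtype=int)
        preds = PredictionSet(y, y, n_classes=2)
        lo, hi, point = bootstrap_ci(preds, accuracy_metric, n_boot=200, seed=0)
        assert (lo, hi, point) == (1.0, 1.0, 1.0)

    def test_interval_contains_point_estimate(self, random_fixtures):
        preds = random_fixtures[0]
        lo, hi, point = bootstrap_ci(preds, accuracy_metric, n_boot=300, seed=1)
        assert lo <= point <= hi

    def test_deterministic_per_seed(self, random_fixtures):
        preds = random_fixtures[1]
        a = bootstrap_ci(preds, accuracy_metric, n_boot=200, seed=7)
        b = bootstrap_ci(preds, accuracy_metric, n_boot=200, seed=7)
        assert a == b

    def test_small_sample_rejected(self):
        y = np.zeros(10, dtype=int)
        with pytest.raises(ValueError, match="30"):
            bootstrap_ci(PredictionSet(y, y, n_classes=2), accuracy_metric)

    def test_coverage_of_true_accuracy(self):
        """Nominal 95% percentile intervals should cover the generating
        accuracy in at least ~90% of simulated prediction sets."""
        true_acc = 0.8
        hits = 0
        n_sims = 200
        for sim in range(n_sims):
            y_true, y_pred = make_prediction_fixture([true_acc] * 4, n=250, seed=1000 + sim)
            preds = PredictionSet(y_true, y_pred, n_classes=4)
            lo, hi, _ = bootstrap_ci(preds, accuracy_metric, n_boot=300, seed=sim)
            hits += lo <= true_acc <= hi
        assert hits / n_sims >= 0.90


class TestPredictionSetValidation:
    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            PredictionSet([0, 1], [0])

    def test_probability_rows_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            PredictionSet([0], [0], np.array([[0.5, 0.2]]), n_classes=2)
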