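"""Roster learners, cost-sensitive thresholds and confusion-matrix metrics."""

import numpy as np
import pytest

from kinomeprio.classify import (
    ClassifierSpec,
    ConfusionMatrix,
    ROSTER_NAMES,
    cost_sensitive_wrap,
    cross_validate,
    default_roster,
    derive_seed,
    metrics_from_confusion,
)
from kinomeprio.datamodel_io import Label
from kinomeprio.feature_build import Attribute, FeatureMatrix


def _separable_matrix(n_per_class=30, seed=0, flip=0):
    """Numeric matrix where feature x separates the classes perfectly
    (optionally with `flip` labels swapped)."""
    rng = np.random.default_rng(seed)
    x = np.concatenate([rng.normal(0, 0.3, n_per_class), rng.normal(4, 0.3, n_per_class)])
    z = rng.normal(0, 1, 2 * n_per_class)
    labels = np.array([0] * n_per_class + [1] * n_per_class)
    if flip:
        idx = rng.choice(2 * n_per_class, size=flip, replace=False)
        labels[idx] = 1 - labels[idx]
    attrs = [Attribute("x", "numeric"), Attribute("z", "numeric")]
    rows = [[float(a), float(b)] for a, b in zip(x, z)]
    return FeatureMatrix(attrs, rows, [Label.DISEASE if l else Label.NON_DISEASE
                                       for l in labels])


class TestMetricsArithmetic:
    def test_perfect_classifier(self):
        m = metrics_from_confusion(ConfusionMatrix(10, 0, 10, 0))
        assert (m.tp_rate, m.fp_rate, m.accuracy, m.precision, m.recall, m.f_measure) == \
            (1.0, 0.0, 1.0, 1.0, 1.0, 1.0)

    def test_combined_row_arithmetic(self):
        m = metrics_from_confusion(ConfusionMatrix(tp=223, fn=3, tn=328, fp=3))
        assert m.accuracy == pytest.approx(551 / 557)
        assert round(m.accuracy, 3) == 0.989
        assert round(m.precision, 3) == 0.987 and round(m.recall, 3) == 0.987

    def test_undefined_precision_marked(self):
        m = metrics_from_confusion(ConfusionMatrix(tp=0, fn=5, tn=5, fp=0))
        assert m.precision is None and m.f_measure is None

    def test_empty_confusion_rejected(self):
        with pytest.raises(ValueError):
            metrics_from_confusion(ConfusionMatrix(0, 0, 0, 0))

    def test_class_averaged_recall(self):
        m = metrics_from_confusion(ConfusionMatrix(tp=8, fn=2, tn=9, fp=1))
        assert m.class_averaged()["recall"] == pytest.approx((0.8 + 0.9) / 2)


class TestCostSensitive:
    def test_symmetric_costs_give_half_threshold(self):
        spec = ClassifierSpec("SVM")
        assert spec.threshold == pytest.approx(0.5)

    def test_threshold_closed_form(self):
        # predict disease when P(D)*cost(FN) >= P(ND)*cost(FP)
        # -> threshold = cost(FP)/(cost(FP)+cost(FN)) = 1/(1+3) = 0.25
        spec = cost_sensitive_wrap(ClassifierSpec("SVM"), ((0, 1), (3, 0)))
        assert spec.threshold == pytest.approx(0.25)

    def test_zero_cost_matrix_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            cost_sensitive_wrap(ClassifierSpec("SVM"), ((0, 0), (0, 0)))

    def test_negative_cost_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            cost_sensitive_wrap(ClassifierSpec("SVM"), ((0, -1), (1, 0)))

    def test_raising_fn_cost_never_decreases_tp(self):
        """Monotone threshold property on a fixed probability set."""
        probs = np.linspace(0.01, 0.99, 50)
        y = (probs > 0.4).astype(int)
        prev_tp = -1
        for cost_fn in (0.5, 1, 2, 4, 8):
            threshold = 1.0 / (1.0 + cost_fn)
            tp = int(((probs >= threshold) & (y == 1)).sum())
            assert tp >= prev_tp
            prev_tp = tp


class TestCrossValidation:
    def test_separable_data_is_learned_perfectly(self):
        matrix = _separable_matrix()
        for name in ("J48 (Tree)", "SVM", "Naive Bayes"):
            cm, report, model, oof = cross_validate(ClassifierSpec(name), matrix, k=5, seed=0)
            assert report.accuracy == 1.0
            assert report.fp_rate == 0.0

    def test_every_instance_tested_exactly_once(self):
        matrix = _separable_matrix()
        _, _, _, oof = cross_validate(ClassifierSpec("Naive Bayes"), matrix, k=5, seed=0)
        assert np.isfinite(oof).all()

    def test_confusion_totals_match_class_counts(self, small_matrix):
        cm, _, _, _ = cross_validate(ClassifierSpec("J48 (Tree)"), small_matrix, k=5, seed=0)
        y = small_matrix.y()
        assert cm.tp + cm.fn == int(y.sum())
        assert cm.tn + cm.fp == int(len(y) - y.sum())

    def test_shuffled_labels_reach_majority_baseline_only(self):
        """With labels random, CV accuracy hovers at the majority-class share."""
        rng = np.random.default_rng(3)
        accs = []
        for rep in range(5):
            matrix = _separable_matrix(n_per_class=40, seed=rep)
            labels = [Label.DISEASE if v else Label.NON_DISEASE
                      for v in rng.permutation([0, 1] * 40)]
            shuffled = FeatureMatrix(matrix.attributes, matrix.rows, labels)
            _, report, _, _ = cross_validate(ClassifierSpec("J48 (Tree)"), shuffled,
                                             k=5, seed=rep)
            accs.append(report.accuracy)
        assert abs(np.mean(accs) - 0.5) < 0.1

    def test_k_larger_than_minority_class_rejected(self):
        matrix = _separable_matrix(n_per_class=4)
        with pytest.raises(ValueError, match="minority"):
            cross_validate(ClassifierSpec("SVM"), matrix, k=10, seed=0)

    def test_single_class_rejected(self):
        matrix = _separable_matrix(n_per_class=10)
        one_class = FeatureMatrix(matrix.attributes, matrix.rows,
                                  [Label.DISEASE] * matrix.n_instances)
        with pytest.raises(ValueError, match="both classes"):
            cross_validate(ClassifierSpec("SVM"), one_class, k=5, seed=0)


class TestRoster:
    def test_default_roster_has_the_11_members(self):
        assert tuple(s.name for s in default_roster()) == ROSTER_NAMES
        assert len(ROSTER_NAMES) == 11

    @pytest.mark.parametrize("name", ROSTER_NAMES)
    def test_each_member_yields_probabilities(self, name, small_matrix):
        cm, report, model, oof = cross_validate(ClassifierSpec(name), small_matrix,
                                                k=5, seed=1)
        assert ((oof >= 0) & (oof <= 1)).all()
        probs = model.predict_proba(small_matrix)
        assert ((probs >= 0) & (probs <= 1)).all()
        # an informative learner on separable synthetic data beats the
        # majority-class baseline out of fold
        assert report.accuracy > 0.6

    def test_trained_model_rejects_schema_mismatch(self, small_matrix):
        _, _, model, _ = cross_validate(ClassifierSpec("Naive Bayes"), small_matrix,
                                        k=5, seed=0)
        from kinomeprio.feature_build import apply_selection

        other = apply_selection(small_matrix, list(small_matrix.attribute_names[:5]))
        with pytest.raises(ValueError, match="schema"):
            model.predict_proba(other)

    def test_unknown_classifier_rejected(self, small_matrix):
        with pytest.raises(ValueError, match="unknown classifier"):
            cross_validate(ClassifierSpec("AdaBoost"), small_matrix, k=5, seed=0)


class TestSeedDerivation:
    def test_deterministic_and_bounded(self):
        assert derive_seed(1, "folds") == derive_seed(1, "folds")
        assert derive_seed(1, "folds") != derive_seed(2, "folds")
        assert 0 <= derive_seed(12345, "x") < 2**31

    def test_cv_is_reproducible(self, small_matrix):
        a = cross_validate(ClassifierSpec("Random Forest"), small_matrix, k=5, seed=9)
        b = cross_validate(ClassifierSpec("Random Forest"), small_matrix, k=5, seed=9)
        assert a[0] == b[0]
        assert np.allclose(a[3], b[3])
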