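"""Canonical projection, weighted SVM, cross-validation and the NLR search."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from osteoimpact.classification import (
    ConfusionCounts,
    CostMatrix,
    accuracy_metric,
    anova_oneway,
    canonical_projection,
    crossing_detection_rate,
    kfold_cv,
    nlr,
    optimize_cost_matrix,
    train_weighted_classifier,
)
from osteoimpact.synthetic_data import generate_overlapping_projection


def feature_frame(X, y):
    df = pd.DataFrame(X, columns=["tau_ms", "lambda", "dtau_ms", "dlambda"])
    df["label"] = y
    return df


def separable_clusters(n=40, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack(
        [rng.normal(0, 0.3, size=(n, 2)), rng.normal(5, 0.3, size=(n, 2))]
    )
    y = np.array(["Bone"] * n + ["Crossing"] * n)
    return X, y


class TestCanonicalProjection:
    def test_axis_aligned_separation_loads_on_tau(self):
        rng = np.random.default_rng(0)
        n = 50
        X = rng.normal(0, 1, size=(2 * n, 4))
        X[n:, 0] += 8.0  # classes differ only along tau
        y = np.array(["Bone"] * n + ["Crossing"] * n)
        proj = canonical_projection(feature_frame(X, y))
        assert abs(proj.c1[0]) > 0.9
        assert np.linalg.norm(proj.c1) == pytest.approx(1.0)
        assert np.linalg.norm(proj.c2) == pytest.approx(1.0)
        assert abs(proj.c1 @ proj.c2) < 1e-8

    def test_four_point_worked_example(self):
        # Class A at tau 0 and 1, class B at tau 4 and 5, all other
        # features constant: the Fisher direction is the tau axis.  Points
        # are replicated to satisfy the minimum class size; replication
        # leaves the discriminant direction unchanged.
        A = [(0, 0, 0, 0), (1, 0, 0, 0)]
        B = [(4, 0, 0, 0), (5, 0, 0, 0)]
        X = np.array(A * 3 + B * 3, dtype=float)
        y = np.array(["Bone"] * 6 + ["Crossing"] * 6)
        proj = canonical_projection(feature_frame(X, y))
        assert abs(proj.c1[0]) == pytest.approx(1.0, abs=1e-8)

    def test_identical_class_means_rejected(self):
        rng = np.random.default_rng(1)
        X = rng.normal(0, 1, size=(20, 4))
        X = np.vstack([X, X])  # same points in both classes
        y = np.array(["Bone"] * 20 + ["Crossing"] * 20)
        with pytest.raises(ValueError, match="identical class means"):
            canonical_projection(feature_frame(X, y))

    def test_small_class_rejected(self):
        X = np.random.default_rng(2).normal(size=(8, 4))
        y = np.array(["Bone"] * 6 + ["Crossing"] * 2)
        with pytest.raises(ValueError, match="at least 5"):
            canonical_projection(feature_frame(X, y))

    def test_projection_yields_two_columns(self):
        rng = np.random.default_rng(3)
        X = rng.normal(0, 1, size=(30, 4))
        X[:15, 0] += 4
        y = np.array(["Crossing"] * 15 + ["Bone"] * 15)
        proj = canonical_projection(feature_frame(X, y))
        assert proj.transform(X).shape == (30, 2)


class TestWeightedClassifier:
    @pytest.mark.parametrize("sigma_cb", [0.5, 1.0, 3.5, 10.0])
    def test_separable_clusters_perfectly_classified(self, sigma_cb):
        X, y = separable_clusters()
        clf = train_weighted_classifier(X, y, CostMatrix(sigma_cb=sigma_cb))
        assert np.all(clf.predict(X) == y)

    def test_symmetric_costs_match_unweighted_boundary(self):
        X, y = generate_overlapping_projection(n=200, seed=5)
        clf_sym = train_weighted_classifier(X, y, CostMatrix(sigma_cb=2.0, sigma_bc=2.0))
        clf_plain = train_weighted_classifier(X, y, CostMatrix())
        # same ratio => same decision boundary direction
        w_sym = clf_sym.coef_[0] / np.linalg.norm(clf_sym.coef_[0])
        w_plain = clf_plain.coef_[0] / np.linalg.norm(clf_plain.coef_[0])
        assert np.all(clf_sym.predict(X) == clf_plain.predict(X))
        assert w_sym == pytest.approx(w_plain, abs=1e-3)

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 2))
        with pytest.raises(ValueError, match="both classes"):
            train_weighted_classifier(X, np.array(["Bone"] * 10), CostMatrix())

    def test_raising_fn_cost_reduces_false_negatives(self):
        X, y = generate_overlapping_projection(n=400, positive_fraction=0.15, seed=7)
        fn1 = kfold_cv(X, y, CostMatrix(sigma_cb=1.0), seed=7).counts.fn
        fn35 = kfold_cv(X, y, CostMatrix(sigma_cb=3.5), seed=7).counts.fn
        assert fn35 <= fn1

    def test_diagonal_costs_must_be_zero(self):
        with pytest.raises(ValueError, match="diagonal"):
            CostMatrix(sigma_bb=1.0)


class TestCrossValidation:
    def test_every_record_predicted_exactly_once(self):
        X, y = generate_overlapping_projection(n=100, seed=1)
        res = kfold_cv(X, y, k=5, seed=1)
        assert len(res.predictions) == 100
        assert res.counts.total == 100
        assert len(res.per_fold_accuracy) == 5

    def test_separable_data_has_no_errors(self):
        X, y = separable_clusters(n=30, seed=2)
        res = kfold_cv(X, y, k=5, seed=2)
        assert res.counts.fp == 0 and res.counts.fn == 0
        assert res.counts.accuracy == 1.0

    def test_class_smaller_than_k_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 2))
        y = np.array(["Bone"] * 7 + ["Crossing"] * 3)
        with pytest.raises(ValueError, match="fewer than k"):
            kfold_cv(X, y, k=5, seed=0)


class TestMetrics:
    def test_nlr_worked_example(self):
        assert nlr(ConfusionCounts(tp=90, fn=10, tn=80, fp=20)) == pytest.approx(0.125)

    def test_nlr_zero_when_no_misses(self):
        assert nlr(ConfusionCounts(tp=10, fn=0, tn=50, fp=5)) == 0.0

    def test_nlr_one_for_uninformative_test(self):
        assert nlr(ConfusionCounts(tp=25, fn=25, tn=30, fp=30)) == pytest.approx(1.0)

    def test_nlr_degenerate_counts_named(self):
        with pytest.raises(ZeroDivisionError, match="TP\\+FN"):
            nlr(ConfusionCounts(tp=0, fn=0, tn=10, fp=5))
        with pytest.raises(ZeroDivisionError, match="TN=0"):
            nlr(ConfusionCounts(tp=5, fn=5, tn=0, fp=5))

    def test_accuracy_examples(self):
        assert accuracy_metric(ConfusionCounts(tp=10, tn=10, fp=0, fn=0)) == 1.0
        assert accuracy_metric(ConfusionCounts(tp=25, tn=25, fp=25, fn=25)) == 0.5
        with pytest.raises(ValueError):
            accuracy_metric(ConfusionCounts(tp=0, tn=0, fp=0, fn=0))

    @given(
        tp=st.integers(0, 200),
        tn=st.integers(1, 200),
        fp=st.integers(0, 200),
        fn=st.integers(0, 200),
    )
    def test_metrics_match_brute_force_recount(self, tp, tn, fp, fn):
        """Rebuild label/prediction vectors and recount from scratch."""
        if tp + fn == 0:
            return
        y = ["Crossing"] * (tp + fn) + ["Bone"] * (tn + fp)
        pred = (
            ["Crossing"] * tp + ["Bone"] * fn + ["Bone"] * tn + ["Crossing"] * fp
        )
        correct = sum(a == b for a, b in zip(y, pred))
        counts = ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)
        assert accuracy_metric(counts) == pytest.approx(correct / len(y))
        miss_rate = sum(
            1 for a, b in zip(y, pred) if a == "Crossing" and b == "Bone"
        ) / (tp + fn)
        spec = tn / (tn + fp)
        assert nlr(counts) == pytest.approx(miss_rate / spec)


class TestCostMatrixSearch:
    def test_separable_ties_break_to_unit_cost(self):
        X, y = separable_clusters(n=25, seed=3)
        search = optimize_cost_matrix(X, y, k=5, seed=3, sigma_grid=np.arange(1, 5.25, 0.25))
        assert search.cost.sigma_cb == 1.0
        assert search.nlr_value == 0.0

    def test_unit_cell_reproduces_unweighted_counts(self):
        X, y = generate_overlapping_projection(n=300, seed=9)
        search = optimize_cost_matrix(X, y, k=5, seed=9, sigma_grid=np.array([1.0, 2.0, 3.5]))
        plain = kfold_cv(X, y, CostMatrix(), k=5, seed=9)
        assert search.counts_unweighted == plain.counts

    def test_monotone_cost_response_on_fixed_folds(self):
        X, y = generate_overlapping_projection(n=600, positive_fraction=0.15, seed=7)
        search = optimize_cost_matrix(X, y, k=5, seed=7)
        fn = np.array(search.fn_curve)
        fp = np.array(search.fp_curve)
        # monotone up to small CV wiggle
        assert np.all(np.diff(fn) <= 2)
        assert fn[-1] <= fn[0]
        assert np.all(np.diff(fp) >= -2)
        assert fp[-1] >= fp[0]
        assert search.nlr_value <= search.nlr_unweighted


class TestAnova:
    def test_identical_groups_give_zero_f(self):
        v = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        y = np.array(["Bone"] * 3 + ["Crossing"] * 3)
        f, p = anova_oneway(v, y)
        assert f == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_f_statistic(self):
        v = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = np.array(["Bone"] * 3 + ["Crossing"] * 3)
        f, p = anova_oneway(v, y)
        assert f == pytest.approx(13.5)

    def test_two_group_f_equals_t_squared(self):
        from scipy.stats import ttest_ind

        rng = np.random.default_rng(4)
        a = rng.normal(0, 1, 20)
        b = rng.normal(0.8, 1, 25)
        v = np.concatenate([a, b])
        y = np.array(["Bone"] * 20 + ["Crossing"] * 25)
        f, _ = anova_oneway(v, y)
        t, _ = ttest_ind(a, b, equal_var=True)
        assert f == pytest.approx(t**2)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            anova_oneway(np.ones(5), np.array(["Bone"] * 5))


class TestDetectionRate:
    def test_shifted_prediction_counts_as_detection(self):
        table = pd.DataFrame(
            {
                "plate_id": ["p"] * 5,
                "impact_index": [2, 3, 4, 5, 6],
                "label": ["Bone", "Bone", "Bone", "Crossing", "Crossing"],
            }
        )
        # crossing flagged one impact early only
        preds = np.array(["Bone", "Bone", "Crossing", "Bone", "Crossing"])
        assert crossing_detection_rate(table, preds) == pytest.approx(1.0)
        # no prediction near impact 5 or 6
        preds2 = np.array(["Crossing", "Bone", "Bone", "Bone", "Bone"])
        assert crossing_detection_rate(table, preds2) == 0.0
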