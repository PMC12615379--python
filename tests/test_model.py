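"""Balancing, classifier training, evaluation and report identities."""

import numpy as np
import pandas as pd
import pytest

from paddyspec import (
    ClassificationReport,
    ScenarioConfig,
    balance_classes,
    evaluate,
    train_classifier,
)
from paddyspec.model import predict_labels, split_pixels

TINY_GRID = {
    "learning_rate": [0.3],
    "n_estimators": [30],
    "max_depth": [3],
    "min_child_weight": [1],
    "gamma": [0.0],
}


def _labelled_blobs(rng, counts, gap=4.0, d=3):
    X, y = [], []
    for i, (lab, n) in enumerate(counts.items()):
        X.append(rng.normal(i * gap, 1.0, size=(n, d)))
        y += [lab] * n
    return pd.DataFrame(np.vstack(X), columns=[f"f{j}" for j in range(d)]), np.array(y)


class TestBalanceClasses:
    def test_majority_classes_reduced_to_minority_size(self, rng):
        X, y = _labelled_blobs(rng, {"mild": 100, "moderate": 700, "severe": 60})
        Xb, yb = balance_classes(X, y, seed=0)
        counts = pd.Series(yb).value_counts()
        assert set(counts) == {60}
        assert len(Xb) == 180

    def test_already_balanced_input_unchanged(self, rng):
        X, y = _labelled_blobs(rng, {"mild": 50, "moderate": 50, "severe": 50})
        Xb, yb = balance_classes(X, y, seed=0)
        assert len(Xb) == 150
        assert (pd.Series(yb).value_counts() == 50).all()

    def test_centroids_stay_inside_class_hull(self, rng):
        X, y = _labelled_blobs(rng, {"a": 30, "b": 300}, gap=10.0)
        Xb, yb = balance_classes(X, y, seed=0)
        b_orig = X[y == "b"].to_numpy()
        b_cent = Xb[yb == "b"].to_numpy()
        assert b_cent.min() >= b_orig.min() - 1e-9
        assert b_cent.max() <= b_orig.max() + 1e-9
        # centroids separate from the other class's region
        assert b_cent.mean() > 5.0

    def test_minority_class_untouched(self, rng):
        X, y = _labelled_blobs(rng, {"a": 20, "b": 100})
        Xb, yb = balance_classes(X, y, seed=0)
        assert np.allclose(
            np.sort(Xb[yb == "a"].to_numpy(), axis=0),
            np.sort(X[y == "a"].to_numpy(), axis=0),
        )

    def test_tiny_minority_rejected(self, rng):
        X, y = _labelled_blobs(rng, {"a": 1, "b": 50})
        with pytest.raises(ValueError):
            balance_classes(X, y)


class TestTrainClassifier:
    def test_separable_classes_reach_high_cv_oa(self, rng):
        X, y = _labelled_blobs(
            rng, {"mild": 60, "moderate": 60, "severe": 60}, gap=8.0
        )
        cfg = ScenarioConfig(cv_folds=3, param_grid=TINY_GRID, seed=0)
        _, summary = train_classifier(X, y, cfg)
        assert summary["cv_oa_mean_pct"] > 95
        assert "±" in summary["cv_oa"]

    def test_fixed_seed_reproduces_selection(self, rng):
        X, y = _labelled_blobs(rng, {"mild": 40, "moderate": 40, "severe": 40})
        grid = dict(TINY_GRID, learning_rate=[0.1, 0.3], max_depth=[2, 3])
        cfg = ScenarioConfig(cv_folds=3, param_grid=grid, seed=7)
        _, s1 = train_classifier(X, y, cfg)
        _, s2 = train_classifier(X, y, cfg)
        assert s1["params"] == s2["params"]
        assert s1["cv_oa_mean_pct"] == s2["cv_oa_mean_pct"]

    def test_single_class_rejected(self, rng):
        X, y = _labelled_blobs(rng, {"mild": 50})
        with pytest.raises(ValueError):
            train_classifier(X, y, ScenarioConfig(param_grid=TINY_GRID))


class TestEvaluate:
    def test_perfect_predictions(self, rng):
        X, y = _labelled_blobs(rng, {"mild": 40, "moderate": 40, "severe": 40}, gap=10.0)
        cfg = ScenarioConfig(cv_folds=3, param_grid=TINY_GRID, seed=0)
        model, _ = train_classifier(X, y, cfg)
        report = evaluate(model, X, y)
        assert report.oa_pct == 100.0
        assert all(v == 100.0 for v in report.ua_pct.values())
        assert all(v == 100.0 for v in report.pa_pct.values())

    def test_hand_computed_confusion_accuracies(self):
        cm = np.array([[50, 10, 0], [5, 40, 5], [0, 10, 40]])
        y_true = np.repeat(["mild", "moderate", "severe"], [60, 50, 50])
        y_pred = (
            ["mild"] * 50 + ["moderate"] * 10
            + ["mild"] * 5 + ["moderate"] * 40 + ["severe"] * 5
            + ["moderate"] * 10 + ["severe"] * 40
        )
        report = ClassificationReport.from_predictions(y_true, y_pred)
        assert np.array_equal(report.confusion, cm)
        assert report.oa_pct == pytest.approx(100 * 130 / 160)  # 81.25
        assert report.pa_pct["mild"] == pytest.approx(100 * 50 / 60)
        assert report.ua_pct["mild"] == pytest.approx(100 * 50 / 55)
        assert report.misclassification_pct["moderate"]["mild"] == pytest.approx(10.0)
        report.check_identities()

    def test_all_one_class_predictor_on_balanced_test(self):
        y_true = np.repeat(["mild", "moderate", "severe"], 30)
        y_pred = ["moderate"] * 90
        report = ClassificationReport.from_predictions(y_true, y_pred)
        assert report.oa_pct == pytest.approx(100 / 3)
        assert np.isnan(report.ua_pct["mild"])  # nothing predicted mild

    def test_absent_true_class_flagged_nan_pa(self):
        report = ClassificationReport.from_predictions(
            ["mild", "mild"], ["mild", "moderate"]
        )
        assert np.isnan(report.pa_pct["severe"])


class TestSplit:
    def test_pixel_split_is_stratified_and_seeded(self, rng):
        X, y = _labelled_blobs(rng, {"mild": 100, "moderate": 200, "severe": 50})
        X["plot_id"] = np.arange(len(X)) % 10
        cfg = ScenarioConfig(seed=3)
        Xtr, Xte, ytr, yte = split_pixels(X, y, X["plot_id"], cfg)
        assert len(Xte) == pytest.approx(0.3 * len(X), abs=2)
        frac_te = (yte == "severe").mean()
        assert frac_te == pytest.approx((y == "severe").mean(), abs=0.02)
        Xtr2, *_ = split_pixels(X, y, X["plot_id"], cfg)
        assert list(Xtr.index) == list(Xtr2.index)

    def test_plot_split_keeps_plots_whole(self, rng):
        X, y = _labelled_blobs(rng, {"mild": 90, "moderate": 90, "severe": 90})
        plot = np.repeat(np.arange(27), 10)
        cfg = ScenarioConfig(seed=0, split_by="plot")
        Xtr, Xte, ytr, yte = split_pixels(X, y, plot, cfg)
        tr_plots = set(plot[Xtr.index])
        te_plots = set(plot[Xte.index])
        assert tr_plots.isdisjoint(te_plots)

    def test_no_test_leakage_through_balancing(self, rng):
        """Balancing the training half never alters the test rows."""
        X, y = _labelled_blobs(rng, {"mild": 60, "moderate": 200, "severe": 40})
        X["plot_id"] = 0
        cfg = ScenarioConfig(seed=1)
        Xtr, Xte, ytr, yte = split_pixels(X, y, X["plot_id"], cfg)
        before = Xte.copy()
        balance_classes(Xtr.drop(columns="plot_id"), ytr, seed=0)
        pd.testing.assert_frame_equal(before, Xte)


def test_predict_labels_decodes_to_severity_strings(rng):
    X, y = _labelled_blobs(rng, {"mild": 40, "moderate": 40, "severe": 40}, gap=8.0)
    cfg = ScenarioConfig(cv_folds=3, param_grid=TINY_GRID, seed=0)
    model, _ = train_classifier(X, y, cfg)
    preds = predict_labels(model, X)
    assert set(preds) <= {"mild", "moderate", "severe"}
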