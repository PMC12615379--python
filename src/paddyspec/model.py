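"""Class balancing, severity classification and accuracy reporting.

Early-infestation fields are dominated by moderately infested plots, so the
training set is balanced by centroid undersampling: each majority class is
replaced by the k-means centroids of its samples, k equal to the minority
class size.  A gradient-boosted tree classifier (XGBoost) is then tuned by
grid search on mean 10-fold cross-validated overall accuracy and judged on
an untouched test split via the confusion matrix: overall accuracy (OA),
per-class user's accuracy (UA, precision), producer's accuracy (PA, recall)
and the per-true-class misclassification structure.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.cluster import KMeans
from sklearn.model_selection import StratifiedKFold, train_test_split

from .grading import SEVERITY_LEVELS

__all__ = [
    "ScenarioConfig",
    "ClassificationReport",
    "balance_classes",
    "train_classifier",
    "evaluate",
    "split_pixels",
]

#: Hyperparameter grid centred on the regime reported for this kind of
#: canopy-pixel severity model: learning rate (LR), number of estimators
#: (NE), maximum depth (MD), minimum child weight (MCW) and gamma (GAM).
DEFAULT_GRID = {
    "learning_rate": [0.25, 0.3, 0.35, 0.4],
    "n_estimators": [200, 300, 400],
    "max_depth": [4, 6, 8],
    "min_child_weight": [1, 2],
    "gamma": [0.0],
}


@dataclass
class ScenarioConfig:
    """One experimental scenario: feature/label source and model protocol.

    ``name`` is Dual-DF (dual-date difference features, dual-date labels) or
    Mono-T1 / Mono-T2 (single-date vegetation indices and labels).  Samples
    are pixels, split 7:3 into training and test; hyperparameters are tuned
    by ``cv_folds``-fold cross-validation on the balanced training set.  A
    single master seed drives the split, folds, k-means and boosting.
    """

    name: str = "Dual-DF"
    test_fraction: float = 0.3
    cv_folds: int = 10
    param_grid: dict = field(default_factory=lambda: dict(DEFAULT_GRID))
    seed: int = 0
    #: split pixels independently (mirrors the sample-level protocol) or by
    #: whole plots ("plot") to avoid plot-structure leakage
    split_by: str = "pixel"


@dataclass
class ClassificationReport:
    """Confusion matrix and the accuracy figures derived from it.

    Rows of ``confusion`` are true classes, columns predicted, in
    ``class_order``.  OA/UA/PA are percentages; a class absent from the test
    set has NaN PA (flagged, not silently 0).
    """

    confusion: np.ndarray
    class_order: tuple
    oa_pct: float
    ua_pct: dict
    pa_pct: dict
    misclassification_pct: dict

    @classmethod
    def from_predictions(cls, y_true, y_pred, class_order=SEVERITY_LEVELS):
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        k = len(class_order)
        index = {lab: i for i, lab in enumerate(class_order)}
        cm = np.zeros((k, k), dtype=int)
        for t, p in zip(y_true, y_pred):
            cm[index[str(t)], index[str(p)]] += 1
        total = cm.sum()
        oa = 100.0 * np.trace(cm) / total if total else float("nan")
        ua, pa, mis = {}, {}, {}
        for i, lab in enumerate(class_order):
            col, row = cm[:, i].sum(), cm[i, :].sum()
            ua[lab] = 100.0 * cm[i, i] / col if col else float("nan")
            pa[lab] = 100.0 * cm[i, i] / row if row else float("nan")
            mis[lab] = {
                other: (100.0 * cm[i, j] / row if row else float("nan"))
                for j, other in enumerate(class_order)
                if j != i
            }
        return cls(
            confusion=cm,
            class_order=tuple(class_order),
            oa_pct=oa,
            ua_pct=ua,
            pa_pct=pa,
            misclassification_pct=mis,
        )

    def check_identities(self) -> None:
        """Assert the confusion-matrix accounting identities exactly."""
        cm = self.confusion
        total = cm.sum()
        assert np.isclose(self.oa_pct, 100.0 * np.trace(cm) / total)
        for i, lab in enumerate(self.class_order):
            if cm[i, :].sum():
                assert np.isclose(self.pa_pct[lab], 100.0 * cm[i, i] / cm[i, :].sum())
            if cm[:, i].sum():
                assert np.isclose(self.ua_pct[lab], 100.0 * cm[i, i] / cm[:, i].sum())


def balance_classes(
    features: pd.DataFrame, labels, seed: int = 0
) -> tuple[pd.DataFrame, np.ndarray]:
    """Centroid undersampling of every majority class.

    Each class larger than the minority class is replaced by the k-means
    centroids of its samples, k = minority-class size; classes already at
    (or below) that size pass through untouched.
    """
    labels = np.asarray(labels).astype(str)
    counts = pd.Series(labels).value_counts()
    if counts.min() < 2:
        raise ValueError("minority class needs at least 2 samples")
    k = int(counts.min())
    X_parts, y_parts = [], []
    for lab in counts.index:
        Xc = features[labels == lab]
        if len(Xc) <= k:
            X_parts.append(Xc.to_numpy(dtype=float))
        else:
            km = KMeans(n_clusters=k, random_state=seed, n_init=3)
            km.fit(Xc.to_numpy(dtype=float))
            X_parts.append(km.cluster_centers_)
        y_parts.append(np.full(len(X_parts[-1]), lab, dtype=object))
    Xb = pd.DataFrame(np.vstack(X_parts), columns=features.columns)
    return Xb, np.concatenate(y_parts)


def _make_model(params: dict, seed: int) -> xgb.XGBClassifier:
    return xgb.XGBClassifier(
        **params, tree_method="hist", n_jobs=1, random_state=seed
    )


def train_classifier(
    features: pd.DataFrame, labels, config: ScenarioConfig
) -> tuple[xgb.XGBClassifier, dict]:
    """Grid-search a boosted-tree severity classifier by CV overall accuracy.

    Returns the model refit on the whole (balanced) training set with the
    best hyperparameters, plus a CV summary: best parameters and the fold
    mean ± sd of overall accuracy in percent.
    """
    X = features.to_numpy(dtype=float)
    y_lab = np.asarray(labels).astype(str)
    classes = [c for c in SEVERITY_LEVELS if c in set(y_lab)]
    if len(classes) < 2:
        raise ValueError("training data must contain at least two classes")
    index = {lab: i for i, lab in enumerate(classes)}
    y = np.array([index[lab] for lab in y_lab])

    keys = list(config.param_grid)
    best = None
    for combo in itertools.product(*(config.param_grid[k] for k in keys)):
        params = dict(zip(keys, combo))
        cv = StratifiedKFold(
            n_splits=config.cv_folds, shuffle=True, random_state=config.seed
        )
        fold_oa = []
        for tr, va in cv.split(X, y):
            model = _make_model(params, config.seed)
            model.fit(X[tr], y[tr])
            fold_oa.append(100.0 * (model.predict(X[va]) == y[va]).mean())
        mean_oa, sd_oa = float(np.mean(fold_oa)), float(np.std(fold_oa, ddof=1))
        if best is None or mean_oa > best["cv_oa_mean_pct"]:
            best = {
                "params": params,
                "cv_oa_mean_pct": mean_oa,
                "cv_oa_sd_pct": sd_oa,
            }
    model = _make_model(best["params"], config.seed)
    model.fit(X, y)
    model.severity_classes_ = tuple(classes)  # label decoding for evaluate()
    summary = dict(best)
    summary["cv_oa"] = f"{best['cv_oa_mean_pct']:.2f} ± {best['cv_oa_sd_pct']:.2f}"
    return model, summary


def predict_labels(model: xgb.XGBClassifier, features: pd.DataFrame) -> np.ndarray:
    classes = model.severity_classes_
    codes = model.predict(features.to_numpy(dtype=float))
    return np.array([classes[int(c)] for c in codes], dtype=object)


def evaluate(
    model: xgb.XGBClassifier, features: pd.DataFrame, labels
) -> ClassificationReport:
    """Score a fitted model on a held-out test set.

    The test set must be untouched by balancing, feature selection and
    tuning; the report carries OA, per-class UA/PA and the per-true-class
    misclassification percentages.
    """
    report = ClassificationReport.from_predictions(
        np.asarray(labels).astype(str), predict_labels(model, features)
    )
    report.check_identities()
    return report


def split_pixels(
    features: pd.DataFrame,
    labels,
    plot_ids,
    config: ScenarioConfig,
) -> tuple:
    """7:3 train/test split, by pixel (default) or by whole plots.

    Returns (X_train, X_test, y_train, y_test).  Pixel-level splitting
    mirrors the sample-level protocol; plot-level splitting keeps all
    pixels of a plot on one side to avoid spatial leakage.
    """
    labels = np.asarray(labels).astype(str)
    plot_ids = np.asarray(plot_ids)
    if config.split_by == "pixel":
        return train_test_split(
            features, labels,
            test_size=config.test_fraction,
            random_state=config.seed,
            stratify=labels,
        )
    if config.split_by != "plot":
        raise ValueError("split_by must be 'pixel' or 'plot'")
    rng = np.random.default_rng(config.seed)
    plot_label = {p: labels[plot_ids == p][0] for p in np.unique(plot_ids)}
    test_plots = set()
    for lab in sorted(set(plot_label.values())):
        plots = sorted(p for p, l in plot_label.items() if l == lab)
        n_test = max(1, round(len(plots) * config.test_fraction))
        test_plots |= set(rng.choice(plots, size=n_test, replace=False).tolist())
    mask = np.array([p in test_plots for p in plot_ids])
    return features[~mask], features[mask], labels[~mask], labels[mask]
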