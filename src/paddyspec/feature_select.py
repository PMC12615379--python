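"""Two-step optimization of the candidate feature set.

Step 1 screens the candidates with an L1-penalized multinomial logistic
regression: features are standardized, the regularization strength is
grid-searched on cross-validated overall accuracy, and only features with a
nonzero coefficient (in any class) at the optimum survive — exact
collinearity collapses onto a single representative.

Step 2 runs recursive feature elimination with a gradient-boosted tree
ranker: the model is fit, features are ranked by gain importance, the
lowest-ranked are dropped, and the cross-validated accuracy is traced
against feature count.  The optimal combination is the smallest set beyond
which adding features improves accuracy by less than a saturation threshold
(default 1 percentage point).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

__all__ = ["SelectionTrace", "lasso_screen", "rfe_select", "default_c_grid"]


@dataclass
class SelectionTrace:
    """Per-step record of a selection run: feature sets and CV accuracy."""

    steps: list = field(default_factory=list)

    def add(self, features: list[str], oa: float, knob: float) -> None:
        self.steps.append({"features": list(features), "oa_pct": oa, "knob": knob})

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n_features": [len(s["features"]) for s in self.steps],
                "oa_pct": [s["oa_pct"] for s in self.steps],
                "knob": [s["knob"] for s in self.steps],
            }
        )


def default_c_grid(n: int = 20) -> np.ndarray:
    """Log-spaced inverse-regularization grid spanning four decades."""
    return np.logspace(-2, 2, n)


def _cv_oa(estimator, X, y, folds: int, seed: int) -> float:
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return float(cross_val_score(estimator, X, y, cv=cv, n_jobs=1).mean() * 100.0)


def _drop_exact_duplicates(X: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str]]:
    """Keep one representative of any group of identical standardized columns.

    Exact collinearity makes the L1 optimum non-unique (the penalty is
    indifferent to how weight is split across copies); canonicalizing keeps
    the first column of each duplicate group.
    """
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    keep, seen = [], {}
    for j in range(Z.shape[1]):
        key = Z[:, j].tobytes()
        if key not in seen:
            seen[key] = j
            keep.append(j)
    return X[:, keep], [names[j] for j in keep]


def lasso_screen(
    features: pd.DataFrame,
    labels,
    c_grid=None,
    cv_folds: int = 5,
    seed: int = 0,
) -> tuple[list[str], SelectionTrace]:
    """L1-regularized multinomial logistic screening of candidate features.

    The regularization strength is chosen by the one-standard-error rule on
    cross-validated overall accuracy: the strongest penalty whose mean CV OA
    is within one fold-SE of the best grid point (parsimony among
    statistically indistinguishable optima).  Returns the surviving feature
    names (nonzero coefficient in any class at that optimum) and a trace of
    survivors/accuracy along the grid.  Raises if every grid point zeroes
    out every coefficient.
    """
    X = features.to_numpy(dtype=float)
    y = pd.Categorical(labels).codes
    names = list(features.columns)
    X, names = _drop_exact_duplicates(X, names)
    if c_grid is None:
        c_grid = default_c_grid()
    trace = SelectionTrace()
    grid_stats, survivors_at = [], {}
    for c in np.asarray(c_grid, dtype=float):
        model = make_pipeline(
            StandardScaler(),
            LogisticRegression(
                l1_ratio=1.0, C=c, solver="saga", max_iter=2000, tol=1e-3,
                random_state=seed,
            ),
        )
        cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        folds = cross_val_score(model, X, y, cv=cv, n_jobs=1) * 100.0
        oa, se = float(folds.mean()), float(folds.std(ddof=1) / np.sqrt(cv_folds))
        model.fit(X, y)
        coef = model.named_steps["logisticregression"].coef_
        mask = np.any(coef != 0, axis=0)
        survivors_at[c] = [n for n, m in zip(names, mask) if m]
        trace.add(survivors_at[c], oa, float(c))
        grid_stats.append((c, oa, se))
    if all(not s for s in survivors_at.values()):
        raise ValueError(
            "over-regularized grid: every coefficient is zero at every grid point"
        )
    best_c, best_oa, best_se = max(grid_stats, key=lambda t: t[1])
    # one-SE rule: strongest penalty statistically tied with the best (and
    # not so strong that nothing survives)
    tied = [c for c, oa, _ in grid_stats if oa >= best_oa - best_se and survivors_at[c]]
    chosen_c = min(tied) if tied else best_c
    return survivors_at[chosen_c], trace


def _ranker(seed: int) -> xgb.XGBClassifier:
    return xgb.XGBClassifier(
        n_estimators=80,
        max_depth=4,
        learning_rate=0.3,
        tree_method="hist",
        n_jobs=1,
        random_state=seed,
    )


def _gain_importance(model: xgb.XGBClassifier, names: list[str]) -> np.ndarray:
    booster = model.get_booster()
    booster.feature_names = [f"f{i}" for i in range(len(names))]
    gains = booster.get_score(importance_type="gain")
    out = np.array([gains.get(f"f{i}", 0.0) for i in range(len(names))])
    if not np.all(np.isfinite(out)):
        raise ValueError("non-finite feature importances")
    return out


def rfe_select(
    features: pd.DataFrame,
    labels,
    saturation_pct: float = 1.0,
    cv_folds: int = 10,
    seed: int = 0,
    step=None,
) -> tuple[list[str], SelectionTrace]:
    """Recursive feature elimination with a saturation stopping rule.

    At each round a gradient-boosted classifier is fit on the surviving
    features, cross-validated accuracy is recorded, and the lowest
    gain-importance features are dropped (by default 5 at a time above 100
    features, then 1 at a time).  The returned set is the smallest one whose
    accuracy is within ``saturation_pct`` points of anything achievable with
    more features — accuracy has saturated beyond it.
    """
    X_all = features.to_numpy(dtype=float)
    y = pd.Categorical(labels).codes
    names = list(features.columns)
    if len(names) < 2:
        raise ValueError("recursive elimination needs at least two features")
    if step is None:
        step = lambda n: 5 if n > 100 else 1  # noqa: E731

    current = list(range(len(names)))
    trace = SelectionTrace()
    history: list[tuple[list[int], float]] = []
    while True:
        X = X_all[:, current]
        oa = _cv_oa(_ranker(seed), X, y, cv_folds, seed)
        history.append((list(current), oa))
        trace.add([names[i] for i in current], oa, float(len(current)))
        if len(current) == 1:
            break
        model = _ranker(seed).fit(X, y)
        imp = _gain_importance(model, [names[i] for i in current])
        drop = min(step(len(current)), len(current) - 1)
        order = np.argsort(imp, kind="stable")  # least important first
        doomed = set(order[:drop])
        current = [c for k, c in enumerate(current) if k not in doomed]

    # scan from the fewest features upward for the saturation point
    history.sort(key=lambda h: len(h[0]))
    oas = [h[1] for h in history]
    chosen = history[-1]
    for i, (feats, oa) in enumerate(history):
        if max(oas[i + 1 :], default=-np.inf) < oa + saturation_pct:
            chosen = (feats, oa)
            break
    return [names[i] for i in chosen[0]], trace
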