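"""Joint band scoring and representative-band picking for DSDI-SL.

Every DSDI band is scored three ways against the severity labels — a Fisher
linear-discriminant ratio, a mean-|SHAP| attribution from a gradient-boosted
tree model, and a one-way ANOVA F statistic.  The three score vectors are
individually min–max normalized across bands and averaged into a joint
indicator.  One representative band is then picked per short-wavelength
subinterval (violet, blue, green, yellow-orange, red, short side of the red
edge) as the within-interval peak of the joint score, and k bands are picked
in the long-wavelength (NIR) region as its most prominent local maxima.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xgboost as xgb
from scipy.signal import find_peaks, peak_prominences
from scipy.stats import f_oneway

from .spectral import SpectralGrid

__all__ = [
    "SubintervalScheme",
    "DEFAULT_SCHEME",
    "lda_score",
    "anova_score",
    "shap_score",
    "joint_indicator",
    "JointScore",
    "pick_representatives",
    "score_table",
]


@dataclass(frozen=True)
class SubintervalScheme:
    """Named wavelength intervals partitioning the sensor range.

    Short-wave intervals are half-open [low, high); the final long-wave
    interval is closed at the top.
    """

    short_wave: tuple = (
        ("violet", 399.0, 450.0),
        ("blue", 450.0, 520.0),
        ("green", 520.0, 580.0),
        ("yellow-orange", 580.0, 630.0),
        ("red", 630.0, 680.0),
        ("red-edge-short", 680.0, 750.0),
    )
    long_wave: tuple = ("long-wave", 750.0, 1006.0)

    def interval_of(self, wavelength: float) -> str:
        for name, lo, hi in self.short_wave:
            if lo <= wavelength < hi:
                return name
        name, lo, hi = self.long_wave
        if lo <= wavelength <= hi:
            return name
        raise ValueError(f"{wavelength} nm falls outside the scheme")


DEFAULT_SCHEME = SubintervalScheme()

#: cap for infinite Fisher ratios: largest finite score times this factor
_INF_CAP_FACTOR = 10.0


def _group_values(values: np.ndarray, labels: np.ndarray) -> list:
    return [values[labels == lab] for lab in np.unique(labels)]


def lda_score(values, labels) -> float:
    """Single-feature Fisher ratio: between-class over within-class variance.

    Between-class variance is the sample-size-weighted variance of the class
    means; within-class is the pooled (maximum-likelihood) class variance.
    A zero within-class variance with separated means gives +inf (capped
    later during normalization).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = _group_values(values, labels)
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >=2 classes with >=2 samples each")
    n = np.array([len(g) for g in groups], dtype=float)
    mu = np.array([g.mean() for g in groups])
    grand = (n * mu).sum() / n.sum()
    between = (n * (mu - grand) ** 2).sum() / n.sum()
    within = (n * np.array([g.var() for g in groups])).sum() / n.sum()
    if within == 0:
        return float("inf") if between > 0 else 0.0
    return float(between / within)


def anova_score(values, labels) -> float:
    """One-way ANOVA F statistic of the feature across severity groups."""
    groups = _group_values(np.asarray(values, dtype=float), np.asarray(labels))
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >=2 classes with >=2 samples each")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stat = f_oneway(*groups).statistic
    return float(stat) if np.isfinite(stat) else float("inf")


#: fixed backing-model hyperparameters for SHAP attributions
SHAP_MODEL_PARAMS = dict(
    n_estimators=120,
    max_depth=4,
    learning_rate=0.3,
    tree_method="hist",
    n_jobs=1,
)


def shap_score(features: np.ndarray, labels, seed: int = 0) -> np.ndarray:
    """Mean absolute SHAP attribution per feature.

    A gradient-boosted tree ensemble with fixed hyperparameters and seed is
    fit to the labels; per-sample TreeSHAP attributions (summed over classes
    in absolute value) are averaged into one non-negative score per feature.
    """
    X = np.asarray(features, dtype=float)
    y = pd.Categorical(labels).codes
    model = xgb.XGBClassifier(
        **SHAP_MODEL_PARAMS, random_state=seed, num_class=len(np.unique(y)),
        objective="multi:softprob",
    )
    model.fit(X, y)
    contribs = model.get_booster().predict(
        xgb.DMatrix(X), pred_contribs=True
    )
    # multiclass: (n, n_class, n_feat + bias); binary: (n, n_feat + bias)
    if contribs.ndim == 3:
        attr = np.abs(contribs[:, :, :-1]).sum(axis=1)
    else:
        attr = np.abs(contribs[:, :-1])
    return attr.mean(axis=0)


def _minmax(scores: np.ndarray) -> np.ndarray:
    """Min–max normalize across bands; a constant vector maps to 0.5."""
    s = np.asarray(scores, dtype=float)
    if np.any(np.isinf(s)):
        finite = s[np.isfinite(s)]
        cap = (np.abs(finite).max() if finite.size else 1.0) * _INF_CAP_FACTOR
        s = np.clip(s, -cap, cap)
    lo, hi = s.min(), s.max()
    if hi == lo:
        warnings.warn("constant score vector: method contributes 0.5 uniformly")
        return np.full_like(s, 0.5)
    return (s - lo) / (hi - lo)


@dataclass
class JointScore:
    """Per-band normalized method scores and their average."""

    wavelengths: np.ndarray
    lda: np.ndarray
    shap: np.ndarray
    anova: np.ndarray
    joint: np.ndarray


def joint_indicator(lda, shap, anova, wavelengths) -> JointScore:
    """Normalize each method's scores across bands and average them.

    Each score vector is min–max normalized (so the indicator is invariant
    to monotone affine rescaling of any one method), then the three are
    averaged with equal weight into a joint score in [0, 1].
    """
    lda_n, shap_n, anova_n = _minmax(lda), _minmax(shap), _minmax(anova)
    return JointScore(
        wavelengths=np.asarray(wavelengths, dtype=float),
        lda=lda_n,
        shap=shap_n,
        anova=anova_n,
        joint=(lda_n + shap_n + anova_n) / 3.0,
    )


def score_dsdi_bands(
    dsdi_values: np.ndarray,
    labels,
    grid: SpectralGrid,
    seed: int = 0,
) -> JointScore:
    """Joint indicator for every DSDI band of a pixel sample."""
    X = np.asarray(dsdi_values, dtype=float)
    labels = np.asarray(labels)
    lda = np.array([lda_score(X[:, j], labels) for j in range(X.shape[1])])
    anova = np.array([anova_score(X[:, j], labels) for j in range(X.shape[1])])
    shap = shap_score(X, labels, seed=seed)
    return joint_indicator(lda, shap, anova, grid.wavelengths)


def _long_wave_peaks(score: np.ndarray, k: int) -> list[int]:
    """Indices of the k most prominent interior local maxima (ties: lower index)."""
    peaks, _ = find_peaks(score)
    if peaks.size:
        prom = peak_prominences(score, peaks)[0]
        order = sorted(range(peaks.size), key=lambda i: (-prom[i], peaks[i]))
        chosen = [int(peaks[i]) for i in order[:k]]
    else:
        chosen = []
    if len(chosen) < k:  # fill from the highest unchosen scores
        rest = [i for i in np.argsort(-score, kind="stable") if i not in chosen]
        chosen += [int(i) for i in rest[: k - len(chosen)]]
    return sorted(chosen)


def pick_representatives(
    score: JointScore,
    scheme: SubintervalScheme = DEFAULT_SCHEME,
    n_long: int = 4,
) -> tuple[list[float], list[float]]:
    """Representative DSDI bands: 6 short-wave + ``n_long`` long-wave.

    Within each short-wave subinterval the band with the highest joint score
    wins (ties to the lower wavelength).  In the long-wave region the
    ``n_long`` most prominent local maxima win, prominence measured above
    the higher flanking minimum; if the region has fewer interior peaks the
    remaining slots go to the highest-scoring bands.
    """
    wl, joint = score.wavelengths, score.joint
    short_picks = []
    for name, lo, hi in scheme.short_wave:
        mask = (wl >= lo) & (wl < hi)
        if not mask.any():
            raise ValueError(f"no grid bands inside the {name} interval")
        idx = np.flatnonzero(mask)
        best = idx[int(np.argmax(joint[idx]))]  # argmax takes the first tie
        short_picks.append(float(wl[best]))
    _, lo, hi = scheme.long_wave
    mask = (wl >= lo) & (wl <= hi)
    if mask.sum() < n_long:
        raise ValueError("long-wave region has fewer bands than requested picks")
    idx = np.flatnonzero(mask)
    local = _long_wave_peaks(joint[idx], n_long)
    long_picks = [float(wl[idx[i]]) for i in local]
    return short_picks, long_picks


def score_table(score: JointScore, scheme: SubintervalScheme, picks) -> pd.DataFrame:
    """Flat CSV-ready table of scores, intervals and the selected flag."""
    short_picks, long_picks = picks
    selected = set(short_picks) | set(long_picks)
    return pd.DataFrame(
        {
            "band_nm": score.wavelengths,
            "lda": score.lda,
            "shap": score.shap,
            "anova": score.anova,
            "joint": score.joint,
            "interval": [scheme.interval_of(w) for w in score.wavelengths],
            "selected": [w in selected for w in score.wavelengths],
        }
    )
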