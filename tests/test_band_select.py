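"""Joint band scoring (LDA / SHAP / ANOVA) and representative-band picking."""

import numpy as np
import pytest
from scipy.stats import f_oneway

from paddyspec import (
    DEFAULT_SCHEME,
    JointScore,
    anova_score,
    joint_indicator,
    lda_score,
    pick_representatives,
    shap_score,
)
from paddyspec.band_select import score_table


def _two_class(rng, mu0, mu1, n=200, sd=1.0):
    x = np.concatenate([rng.normal(mu0, sd, n), rng.normal(mu1, sd, n)])
    y = np.array(["a"] * n + ["b"] * n)
    return x, y


class TestLdaScore:
    def test_identical_distributions_score_near_zero(self, rng):
        x, y = _two_class(rng, 0.0, 0.0, n=2000)
        assert lda_score(x, y) < 0.01

    def test_separated_means_unit_variance(self):
        # two classes at means 0 and 10, equal n, within-variance 1:
        # between = 25, within = 1 -> ratio 25
        rng = np.random.default_rng(0)
        x0 = rng.normal(0, 1, 50000)
        x1 = rng.normal(10, 1, 50000)
        x = np.concatenate([x0 - x0.mean(), x1 - x1.mean() + 10])
        x[: 50000] /= x0.std()
        x[50000:] = (x[50000:] - 10) / x1.std() + 10
        y = np.array(["a"] * 50000 + ["b"] * 50000)
        assert lda_score(x, y) == pytest.approx(25.0, rel=1e-6)

    def test_brute_force_equivalence(self, rng):
        x = rng.normal(size=90)
        y = rng.choice(["a", "b", "c"], size=90)
        n = np.array([(y == c).sum() for c in "abc"])
        mu = np.array([x[y == c].mean() for c in "abc"])
        grand = x.mean() if False else (n * mu).sum() / n.sum()
        between = (n * (mu - grand) ** 2).sum() / n.sum()
        within = sum(((x[y == c] - x[y == c].mean()) ** 2).sum() for c in "abc") / n.sum()
        assert lda_score(x, y) == pytest.approx(between / within, rel=1e-12)

    def test_label_permutation_null_is_small(self, rng):
        x, y = _two_class(rng, 0.0, 3.0, n=500)
        informative = lda_score(x, y)
        nulls = [lda_score(x, rng.permutation(y)) for _ in range(20)]
        assert np.mean(nulls) < 0.02 < informative

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            lda_score([1.0, 2.0], ["a", "b"])


class TestAnovaScore:
    def test_equal_group_means_give_small_f(self, rng):
        x = rng.normal(0, 1, 600)
        y = np.repeat(["a", "b", "c"], 200)
        assert anova_score(x, y) < 3.0

    def test_matches_scipy_and_textbook_computation(self, rng):
        groups = [rng.normal(m, 1.0, 10) for m in (0.0, 1.0, 2.0)]
        x = np.concatenate(groups)
        y = np.repeat(["a", "b", "c"], 10)
        assert anova_score(x, y) == pytest.approx(f_oneway(*groups).statistic)
        # textbook one-way F
        k, n = 3, 10
        grand = x.mean()
        msb = n * sum((g.mean() - grand) ** 2 for g in groups) / (k - 1)
        msw = sum(((g - g.mean()) ** 2).sum() for g in groups) / (k * n - k)
        assert anova_score(x, y) == pytest.approx(msb / msw)

    def test_scale_invariance(self, rng):
        x = rng.normal(0, 1, 300) + np.repeat([0, 1, 2], 100)
        y = np.repeat(["a", "b", "c"], 100)
        assert anova_score(7.5 * x, y) == pytest.approx(anova_score(x, y))


class TestShapScore:
    def test_informative_feature_outranks_noise(self, rng):
        n = 400
        informative = np.repeat([0.0, 1.0, 2.0], n // 3 + 1)[:n]
        X = np.column_stack([informative + rng.normal(0, 0.3, n),
                             rng.normal(size=n), rng.normal(size=n)])
        y = np.repeat(["a", "b", "c"], n // 3 + 1)[:n]
        scores = shap_score(X, y, seed=0)
        assert scores[0] > scores[1] and scores[0] > scores[2]
        assert np.all(scores >= 0)

    def test_constant_feature_scores_zero(self, rng):
        X = np.column_stack([rng.normal(size=200), np.full(200, 3.0)])
        y = np.repeat(["a", "b"], 100)
        assert shap_score(X, y, seed=0)[1] == pytest.approx(0.0, abs=1e-8)

    def test_duplicated_informative_pair_beats_noise(self, rng):
        n = 600
        signal = np.repeat([0.0, 2.0], n // 2) + rng.normal(0, 0.2, n)
        X = np.column_stack([signal, signal, rng.normal(size=n)])
        y = np.repeat(["a", "b"], n // 2)
        s = shap_score(X, y, seed=0)
        assert s[0] + s[1] > s[2]


class TestJointIndicator:
    def test_identical_vectors_average_to_themselves(self):
        v = np.array([0.0, 2.0, 1.0, 4.0])
        js = joint_indicator(v, v, v, wavelengths=[400, 500, 600, 700.0])
        expected = (v - v.min()) / (v.max() - v.min())
        assert np.allclose(js.joint, expected)

    def test_constant_method_contributes_half(self):
        v = np.array([0.0, 1.0, 2.0])
        const = np.full(3, 5.0)
        with pytest.warns(UserWarning):
            js = joint_indicator(v, const, v, wavelengths=[400, 500, 600.0])
        norm = v / 2.0
        assert np.allclose(js.joint, (2 * norm + 0.5) / 3)

    def test_invariant_to_affine_rescaling_of_one_method(self, rng):
        a, b, c = rng.random((3, 10))
        wl = np.arange(10) * 50.0 + 400
        base = joint_indicator(a, b, c, wl).joint
        rescaled = joint_indicator(3.5 * a + 2.0, b, c, wl).joint
        assert np.allclose(base, rescaled)

    def test_infinite_scores_are_capped_not_propagated(self):
        v = np.array([1.0, np.inf, 2.0])
        js = joint_indicator(v, v, v, wavelengths=[400, 500, 600.0])
        assert np.all(np.isfinite(js.joint))
        assert js.joint[1] == 1.0


class TestPickRepresentatives:
    def _score(self, grid, joint):
        return JointScore(
            wavelengths=grid.wavelengths,
            lda=joint, shap=joint, anova=joint, joint=joint,
        )

    def test_planted_peaks_are_recovered(self, grid):
        wl = grid.wavelengths
        joint = np.zeros(wl.size)
        short_targets = [421.0, 487.0, 551.0, 601.0, 661.0, 717.0]
        long_targets = [781.0, 855.0, 925.0, 981.0]
        for t in short_targets + long_targets:
            joint += np.exp(-((wl - t) ** 2) / (2 * 8.0**2))
        short, long = pick_representatives(self._score(grid, joint))
        assert short == short_targets
        assert sorted(long) == long_targets

    def test_unimodal_interval_picks_its_mode(self, grid):
        wl = grid.wavelengths
        joint = np.exp(-((wl - 463.0) ** 2) / 50.0)
        short, _ = pick_representatives(self._score(grid, joint))
        assert 463.0 in short

    def test_ties_break_to_lower_wavelength(self, grid):
        joint = np.zeros(grid.n_bands)
        short, _ = pick_representatives(self._score(grid, joint))
        # flat score: every interval's first band wins
        assert short[0] == 399.0 and short[1] == 451.0

    def test_pick_counts_and_distinctness(self, grid, rng):
        joint = rng.random(grid.n_bands)
        short, long = pick_representatives(self._score(grid, joint), n_long=4)
        assert len(short) == 6 and len(long) == 4
        assert len(set(short) | set(long)) == 10
        for w in short:
            assert w < 750
        for w in long:
            assert w >= 750

    def test_score_table_export(self, grid, rng):
        joint = rng.random(grid.n_bands)
        js = self._score(grid, joint)
        picks = pick_representatives(js)
        tab = score_table(js, DEFAULT_SCHEME, picks)
        assert len(tab) == grid.n_bands
        assert tab["selected"].sum() == 10
        assert set(tab.columns) >= {"band_nm", "lda", "shap", "anova", "joint", "interval"}
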