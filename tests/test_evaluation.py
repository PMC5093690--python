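"""Chronological CV, chance, ITR, and the statistical toolkit."""

import numpy as np
import pytest

import ssvepgrid as sg
from ssvepgrid.decoders import ShrinkageLDA
from ssvepgrid.evaluation import (
    binomial_band,
    binomial_chance_quantile,
    chronological_cv,
    fdr_bh,
    fold_over_chance,
    itr_bits_per_min,
    paired_ttest,
    rm_anova_oneway,
    shuffled_chance,
)


def _separable(n=240, d=12, seed=0):
    rng = np.random.default_rng(seed)
    y = np.tile(np.arange(1, 7), n // 6)
    X = np.zeros((n, d))
    X[np.arange(n), y - 1] = 10.0
    X += 0.01 * rng.standard_normal((n, d))
    return X, y


class TestChronologicalCV:
    def test_fold_structure_240_trials(self):
        X, y = _separable()
        res = chronological_cv(X, y, np.arange(240), k=4, classifier=ShrinkageLDA())
        assert len(res.fold_accuracies) == 4
        assert np.bincount(res.fold_of_trial).tolist() == [60, 60, 60, 60]
        assert res.confusion.sum() == 240
        assert res.confusion.sum(axis=1).tolist() == [40] * 6

    def test_separable_features_give_perfect_accuracy(self):
        X, y = _separable()
        res = chronological_cv(X, y, np.arange(240), classifier=ShrinkageLDA())
        assert res.mean_accuracy == 1.0
        assert np.trace(res.confusion) == 240

    def test_uninformative_features_within_chance_band(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((240, 30))
        y = np.tile(np.arange(1, 7), 40)
        res = chronological_cv(X, y, np.arange(240), classifier=ShrinkageLDA())
        lo, hi = binomial_band(240)
        assert lo <= res.mean_accuracy <= hi

    def test_no_test_fold_leakage_into_fitting(self):
        # the model scoring fold 0 must be fit on folds 1-3 only: refitting
        # it by hand on those trials reproduces fold 0's CV predictions
        X, y = _separable(seed=2)
        res = chronological_cv(X, y, np.arange(240), classifier=ShrinkageLDA())
        clf = ShrinkageLDA().fit(X[60:], y[60:])
        assert np.array_equal(clf.predict(X[:60]), res.predictions[:60])

    def test_remainder_absorbed_by_last_fold(self):
        X, y = _separable(n=246 - 246 % 6)  # 240
        X, y = X[:230], y[:230]
        res = chronological_cv(X, y, np.arange(230), classifier=ShrinkageLDA())
        assert np.bincount(res.fold_of_trial).tolist() == [57, 57, 57, 59]

    def test_errors(self):
        X, y = _separable()
        with pytest.raises(ValueError):
            chronological_cv(X, y, np.arange(240), k=1, classifier=ShrinkageLDA())
        y_sorted = np.sort(y)
        with pytest.raises(ValueError, match="missing class"):
            chronological_cv(X, y_sorted, np.arange(240), classifier=ShrinkageLDA())


class TestShuffledChance:
    def test_mean_near_one_sixth_and_reproducible(self):
        X, y = _separable(seed=3)
        mean1, dist1 = shuffled_chance(X, y, np.arange(240), reps=6, seed=11,
                                       classifier=ShrinkageLDA())
        mean2, dist2 = shuffled_chance(X, y, np.arange(240), reps=6, seed=11,
                                       classifier=ShrinkageLDA())
        assert np.array_equal(dist1, dist2)
        lo, hi = binomial_band(240, alpha=0.001)
        assert lo <= mean1 <= hi

    def test_requires_positive_reps(self):
        X, y = _separable()
        with pytest.raises(ValueError):
            shuffled_chance(X, y, None, reps=0, classifier=ShrinkageLDA())


class TestITR:
    @pytest.mark.parametrize("P,expected", [(0.425, 3.2), (0.633, 9.4), (0.200, 0.1)])
    def test_wolpaw_rates_six_classes_five_seconds(self, P, expected):
        assert round(itr_bits_per_min(P, N=6, T=5.0), 1) == expected

    def test_chance_gives_zero_bits(self):
        assert itr_bits_per_min(1 / 6, N=6, T=3.0) == pytest.approx(0.0, abs=1e-12)

    def test_perfect_accuracy_closed_form(self):
        assert round(itr_bits_per_min(1.0, N=6, T=5.0), 2) == 31.02

    def test_strictly_increasing_above_chance(self):
        ps = np.linspace(1 / 6, 1.0, 50)
        vals = [itr_bits_per_min(p) for p in ps]
        assert np.all(np.diff(vals) > 0)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            itr_bits_per_min(1.2)
        with pytest.raises(ValueError):
            itr_bits_per_min(0.5, N=1)
        with pytest.raises(ValueError):
            itr_bits_per_min(0.5, T=0)


class TestPairedTTest:
    def test_identical_samples(self):
        t, df, p = paired_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (t, df, p) == (0.0, 2, 1.0)

    def test_constant_nonzero_difference(self):
        t, df, p = paired_ttest([2, 2, 2, 2], [1, 1, 1, 1])
        assert t == np.inf and p == 0.0 and df == 3

    def test_hand_computed_statistic(self):
        # differences [1.2, 0.8, 1.1, 0.9, 1.0]: mean 1.0, sd 0.1581,
        # t = 1.0 / (0.1581 / sqrt(5)) = 14.14
        a = np.array([1.2, 0.8, 1.1, 0.9, 1.0])
        t, df, p = paired_ttest(a, np.zeros(5))
        assert round(t, 2) == 14.14
        assert df == 4
        assert p < 1e-3


class TestFDR:
    def test_worked_example(self):
        p = [0.01, 0.02, 0.03, 0.04, 0.2, 0.5]
        reject = fdr_bh(p, q=0.2)
        assert reject.tolist() == [True, True, True, True, False, False]

    def test_all_ones_none_rejected(self):
        assert not fdr_bh([1.0, 1.0, 1.0], q=0.2).any()

    def test_zero_pvalue_rejected(self):
        assert fdr_bh([0.0, 0.9, 0.95], q=0.05)[0]

    def test_monotone_in_q(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=40)
        assert fdr_bh(p, q=0.2).sum() >= fdr_bh(p, q=0.1).sum()

    def test_rejection_set_is_downset_of_p_order(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=25)
        reject = fdr_bh(p, q=0.2)
        if reject.any():
            assert p[reject].max() <= p[~reject].min() or not (~reject).any()

    def test_invalid_pvalues(self):
        with pytest.raises(ValueError):
            fdr_bh([0.5, 1.2])


class TestRMAnova:
    def test_identical_conditions_give_zero_F(self):
        Y = np.tile(np.array([[1.0], [2.0], [3.0]]), (1, 4))
        F, df1, df2, eps, p = rm_anova_oneway(Y)
        assert F == 0.0 and p == 1.0
        assert (df1, df2) == (3, 6)

    def test_two_conditions_equal_paired_t_squared(self):
        rng = np.random.default_rng(6)
        Y = rng.standard_normal((12, 2))
        Y[:, 1] += 0.8
        F, df1, df2, eps, p = rm_anova_oneway(Y)
        t, df, pt = paired_ttest(Y[:, 1], Y[:, 0])
        assert F == pytest.approx(t**2, abs=1e-9)
        assert eps == pytest.approx(1.0)
        assert p == pytest.approx(pt, abs=1e-12)

    def test_spherical_sample_covariance_gives_unit_epsilon(self):
        # whiten columns so the sample covariance is exactly the identity
        rng = np.random.default_rng(7)
        M = rng.standard_normal((8, 3))
        Mc = M - M.mean(axis=0)
        L = np.linalg.cholesky(np.cov(Mc, rowvar=False, ddof=1))
        Y = Mc @ np.linalg.inv(L).T + rng.standard_normal(3)
        _, _, _, eps, _ = rm_anova_oneway(Y)
        assert eps == pytest.approx(1.0, abs=1e-6)

    def test_agrees_with_pingouin(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(8)
        Y = rng.standard_normal((10, 4)) + np.array([0.0, 0.3, 0.6, 0.1])
        F, df1, df2, eps, p = rm_anova_oneway(Y)
        long = pd.DataFrame({
            "subject": np.repeat(np.arange(10), 4),
            "cond": np.tile(np.arange(4), 10),
            "y": Y.ravel(),
        })
        res = pg.rm_anova(data=long, dv="y", within="cond", subject="subject",
                          correction=True)
        assert F == pytest.approx(float(res["F"].iloc[0]), rel=1e-9)
        assert eps == pytest.approx(float(res["eps"].iloc[0]), rel=1e-6)
        assert p == pytest.approx(float(res["p_GG_corr"].iloc[0]), rel=1e-6)

    def test_rejects_missing_cells(self):
        Y = np.ones((4, 3))
        Y[1, 2] = np.nan
        with pytest.raises(ValueError):
            rm_anova_oneway(Y)


class TestFoldOverChance:
    @pytest.mark.parametrize("acc,chance,expected",
                             [(35.81, 17.44, 2.05), (65.83, 17.44, 3.77)])
    def test_reported_ratios(self, acc, chance, expected):
        assert round(fold_over_chance(acc, chance), 2) == expected

    def test_self_ratio_is_one(self):
        assert fold_over_chance(0.42, 0.42) == pytest.approx(1.0)

    def test_requires_positive_chance(self):
        with pytest.raises(ValueError):
            fold_over_chance(0.5, 0.0)


def test_binomial_chance_quantile_exceeds_nominal_rate():
    q95 = binomial_chance_quantile(240, 6, 0.95)
    assert 1 / 6 < q95 < 0.25
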