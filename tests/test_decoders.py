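"""Shrinkage LDA and CCA: closed-form checks and independent oracles."""

import numpy as np
import pytest
from scipy.optimize import minimize
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

import ssvepgrid as sg
from ssvepgrid.decoders import (
    CCAClassifier,
    ShrinkageLDA,
    cca_classify,
    cca_max_correlation,
    fit_shrinkage_lda,
    lda_scores,
    make_cca_references,
    predict_lda,
)


def _gaussian_two_class(n=600, d=5, sep=2.0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, d))
    y = np.repeat([1, 2], n // 2)
    X[y == 1, 0] -= sep / 2
    X[y == 2, 0] += sep / 2
    return X, y


class TestShrinkageLDA:
    def test_zero_shrinkage_matches_classical_lda(self):
        X, y = _gaussian_two_class()
        model = fit_shrinkage_lda(X, y, shrinkage=0.0)
        ours, _ = predict_lda(model, X)
        ref = LinearDiscriminantAnalysis(solver="lsqr").fit(X, y)
        assert np.array_equal(ours, ref.predict(X))

    def test_weight_direction_closed_form(self):
        # means at +/- e1 with isotropic covariance: w1 - w2 parallel to e1
        X, y = _gaussian_two_class(n=20000, sep=2.0, seed=1)
        model = fit_shrinkage_lda(X, y, shrinkage=0.0)
        dw = model.weights[1] - model.weights[0]
        cos = dw[0] / np.linalg.norm(dw)
        assert abs(cos) > np.cos(np.deg2rad(5))

    def test_high_dimensional_regime_invertible(self):
        # d=540 features from n=180 trials: sample covariance is singular,
        # shrunk covariance must be positive definite with floor gamma*nu
        rng = np.random.default_rng(2)
        X = rng.standard_normal((180, 540))
        y = np.tile(np.arange(1, 7), 30)
        model = fit_shrinkage_lda(X, y)
        eigvals = np.linalg.eigvalsh(model.cov)
        assert model.shrinkage > 0
        assert eigvals.min() > 0
        assert eigvals.min() >= 0.999 * model.shrinkage * model.nu

    def test_shrinkage_grows_as_samples_shrink(self):
        # anisotropic covariance (so the identity target is imperfect):
        # the analytic intensity must fall as trials accumulate
        d = 60
        scales = np.sqrt(np.linspace(0.2, 5.0, d))
        gammas = []
        for n in (66, 300, 3000):
            rng = np.random.default_rng(3)
            X = rng.standard_normal((n, d)) * scales
            y = np.tile(np.arange(1, 7), n // 6)
            gammas.append(fit_shrinkage_lda(X, y).shrinkage)
        assert gammas[0] > gammas[1] > gammas[2]

    def test_trial_at_class_mean_predicted_as_that_class(self):
        X, y = _gaussian_two_class()
        model = fit_shrinkage_lda(X, y)
        labels, scores = predict_lda(model, model.means)
        assert list(labels) == [1, 2]
        assert scores.shape == (2, 2)

    def test_column_permutation_invariance(self):
        X, y = _gaussian_two_class(seed=4)
        rng = np.random.default_rng(5)
        perm = rng.permutation(X.shape[1])
        a, _ = predict_lda(fit_shrinkage_lda(X, y), X)
        b, _ = predict_lda(fit_shrinkage_lda(X[:, perm], y), X[:, perm])
        assert np.array_equal(a, b)

    def test_affine_feature_invariance_after_refit(self):
        X, y = _gaussian_two_class(seed=6)
        a, _ = predict_lda(fit_shrinkage_lda(X, y), X)
        Z = 3.7 * X + 11.0
        b, _ = predict_lda(fit_shrinkage_lda(Z, y), Z)
        assert np.array_equal(a, b)

    def test_errors(self):
        X, y = _gaussian_two_class()
        with pytest.raises(ValueError, match="fewer than 2"):
            fit_shrinkage_lda(X[:3], np.array([1, 1, 2]))
        with pytest.raises(ValueError):
            fit_shrinkage_lda(np.full((10, 2), np.nan), np.repeat([1, 2], 5))
        model = fit_shrinkage_lda(X, y)
        with pytest.raises(ValueError, match="dimension"):
            lda_scores(model, X[:, :3])
        with pytest.raises(ValueError):
            fit_shrinkage_lda(X, y, shrinkage=1.5)


class TestCCA:
    def test_exact_reference_copy_gives_one(self):
        t = np.arange(400) / 500.0
        Y = np.vstack([np.sin(2 * np.pi * 6 * t), np.cos(2 * np.pi * 6 * t)])
        X = np.vstack([Y[0], np.random.default_rng(0).standard_normal(400)])
        assert cca_max_correlation(X, Y) == pytest.approx(1.0, abs=1e-9)

    def test_orthogonal_rows_give_zero(self):
        # sinusoids at exact DFT frequencies of the sample grid are orthogonal
        n = 500
        t = np.arange(n) / 500.0
        X = np.sin(2 * np.pi * 10 * t)[None, :]
        Y = np.vstack([np.sin(2 * np.pi * 20 * t), np.cos(2 * np.pi * 20 * t)])
        assert cca_max_correlation(X, Y) == pytest.approx(0.0, abs=1e-9)

    def test_matches_brute_force_optimizer(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((4, 200))
        Y = rng.standard_normal((2, 200))
        rho = cca_max_correlation(X, Y)

        Xc = X - X.mean(axis=1, keepdims=True)
        Yc = Y - Y.mean(axis=1, keepdims=True)

        def neg_corr(p):
            u = p[:4] @ Xc
            v = p[4:] @ Yc
            return -np.corrcoef(u, v)[0, 1]

        best = max(
            -minimize(neg_corr, rng.standard_normal(6), method="Nelder-Mead",
                      options={"maxiter": 5000, "xatol": 1e-10, "fatol": 1e-12}).fun
            for _ in range(8)
        )
        assert rho == pytest.approx(best, abs=1e-4)

    def test_invariance_under_invertible_transforms(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((3, 300))
        Y = rng.standard_normal((2, 300))
        A = rng.standard_normal((3, 3)) + 3 * np.eye(3)
        B = rng.standard_normal((2, 2)) + 3 * np.eye(2)
        assert cca_max_correlation(A @ X, B @ Y) == pytest.approx(
            cca_max_correlation(X, Y), abs=1e-9)

    def test_rejects_degenerate_inputs(self):
        X = np.zeros((2, 100))
        Y = np.vstack([np.ones(100), np.ones(100)])  # rank deficient
        with pytest.raises(ValueError, match="rank"):
            cca_max_correlation(X, Y)
        with pytest.raises(ValueError, match="samples"):
            cca_max_correlation(np.zeros((10, 5)), np.zeros((2, 5)))

    def test_bottom_up_noiseless_is_perfect(self):
        cfg = sg.SynthConfig(seed=9, trials_per_class=3, duration=2.0,
                             noise_pink_amp=0.0, alpha_amp=0.0, intermod_amp=0.0)
        ep = sg.simulate_epochs(cfg, sg.condition("bottom_up"))
        refs = make_cca_references(ep.n_samples, ep.fs, sg.condition("bottom_up"))
        labels, _ = cca_classify(ep, refs)
        assert np.array_equal(labels, ep.labels)

    def test_all_noise_epochs_near_chance(self):
        cfg = sg.SynthConfig(seed=10, trials_per_class=8, duration=2.0,
                             base_amp=0.0, attention_gain=0.0, intermod_amp=0.0)
        ep = sg.simulate_epochs(cfg, sg.condition("top_down"))
        refs = make_cca_references(ep.n_samples, ep.fs, sg.condition("top_down"))
        labels, _ = cca_classify(ep, refs)
        acc = np.mean(labels == ep.labels)
        lo, hi = sg.evaluation.binomial_band(ep.n_trials)
        assert lo <= acc <= hi

    def test_reference_construction(self):
        refs = make_cca_references(1000, 500.0, sg.condition("top_down"),
                                   n_harmonics=2, include_sum=True)
        assert refs.references[4].shape == (10, 1000)  # 2 freqs x 2 harm x 2 + sum pair
        refs_bu = make_cca_references(1000, 500.0, sg.condition("bottom_up"))
        assert refs_bu.references[4].shape == (4, 1000)
        assert refs.frequencies[4] == (5.0, 6.5)


def test_training_accuracy_perfect_on_noiseless_top_down():
    cfg = sg.SynthConfig(seed=11, trials_per_class=4, duration=2.0,
                         attention_gain=3.0, noise_pink_amp=0.0, alpha_amp=0.0)
    ep = sg.simulate_epochs(cfg, sg.condition("top_down"))
    feats = sg.select_channels(sg.psd_features(ep), ep.montage.eeg_channels)
    clf = ShrinkageLDA().fit(feats.matrix, ep.labels)
    assert np.mean(clf.predict(feats.matrix) == ep.labels) == 1.0
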