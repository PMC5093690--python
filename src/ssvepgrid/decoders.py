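"""The two decoders compared by the pipeline: shrinkage LDA and CCA templates.

Shrinkage-regularized LDA is the workhorse for the top-down paradigm: with
540 spectral features and only 180 training trials the pooled within-class
covariance is singular, so it is shrunk toward a scaled identity nu*I with
nu = trace(S)/d, with the analytic (Ledoit-Wolf) shrinkage intensity.

CCA template matching is the classical single-frequency SSVEP decoder kept
as the comparison method: each class is represented by sinusoidal reference
signals (fundamentals plus harmonics, and both class frequencies for the
pair-coded conditions) and a trial is assigned to the class whose reference
set attains the largest canonical correlation with the multichannel epoch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.covariance import ledoit_wolf

from .paradigm import (
    DEFAULT_GRID,
    Condition,
    LineGrid,
    class_frequencies,
    class_sum_frequency,
    letter_class,
)

__all__ = [
    "ShrinkageLDAModel",
    "fit_shrinkage_lda",
    "predict_lda",
    "ShrinkageLDA",
    "CCAReferenceSet",
    "make_cca_references",
    "cca_max_correlation",
    "cca_classify",
    "CCAClassifier",
]

logger = logging.getLogger(__name__)


@dataclass
class ShrinkageLDAModel:
    """Fitted multi-class LDA with a shrunk pooled covariance.

    Scoring is shared-covariance Gaussian: g_c(x) = w_c @ x + b_c with
    w_c = inv(Sigma_shrunk) @ mu_c and b_c = -mu_c @ w_c / 2 + log pi_c.
    """

    classes: np.ndarray
    means: np.ndarray           # n_classes x d
    cov: np.ndarray             # shrunk pooled covariance, d x d
    shrinkage: float            # gamma in [0, 1]
    nu: float                   # shrinkage target scale: trace(S)/d
    weights: np.ndarray         # n_classes x d
    biases: np.ndarray          # n_classes
    priors: np.ndarray

    @property
    def n_features(self) -> int:
        return self.means.shape[1]


def fit_shrinkage_lda(features, labels=None, shrinkage="auto") -> ShrinkageLDAModel:
    """Fit shrinkage LDA on a feature matrix (or a PSDFeatures object).

    ``shrinkage`` is "auto" for the analytic Ledoit-Wolf intensity, or a
    fixed value in [0, 1] (0 recovers classical LDA when the pooled
    covariance is invertible).
    """
    X, labels = _coerce(features, labels)
    if not np.all(np.isfinite(X)):
        raise ValueError("features contain non-finite values")
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    if counts.min() < 2:
        short = classes[counts.argmin()]
        raise ValueError(f"class {short} has fewer than 2 trials")

    n, d = X.shape
    means = np.vstack([X[labels == c].mean(axis=0) for c in classes])
    centered = X - means[np.searchsorted(classes, labels)]

    if shrinkage == "auto":
        cov, gamma = ledoit_wolf(centered, assume_centered=True)
    else:
        gamma = float(shrinkage)
        if not 0.0 <= gamma <= 1.0:
            raise ValueError("shrinkage must lie in [0, 1]")
        S = centered.T @ centered / n
        nu = np.trace(S) / d
        cov = (1.0 - gamma) * S + gamma * nu * np.eye(d)
    nu = float(np.trace(cov) / d) if shrinkage == "auto" else float(nu)

    priors = counts / n
    weights = np.linalg.solve(cov, means.T).T
    biases = -0.5 * np.einsum("cd,cd->c", means, weights) + np.log(priors)
    return ShrinkageLDAModel(
        classes=classes,
        means=means,
        cov=cov,
        shrinkage=float(gamma),
        nu=nu,
        weights=weights,
        biases=biases,
        priors=priors,
    )


def lda_scores(model: ShrinkageLDAModel, features) -> np.ndarray:
    """Per-class discriminant values g_c(x), shape (trials, n_classes)."""
    X, _ = _coerce(features, None, allow_unlabelled=True)
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match model ({model.n_features})"
        )
    return X @ model.weights.T + model.biases


def predict_lda(model: ShrinkageLDAModel, features):
    """Predicted labels and full decision-value matrix.

    Ties are broken deterministically toward the lowest class index and
    logged at DEBUG level.
    """
    scores = lda_scores(model, features)
    best = scores.argmax(axis=1)  # argmax returns the first (lowest) maximizer
    ties = (scores == scores.max(axis=1, keepdims=True)).sum(axis=1) > 1
    if ties.any():
        logger.debug("LDA ties on %d trials broken toward the lowest class", ties.sum())
    return model.classes[best], scores


def _coerce(features, labels, allow_unlabelled=False):
    if hasattr(features, "matrix"):
        X = features.matrix
        if labels is None:
            labels = features.labels
    else:
        X = np.asarray(features, dtype=float)
    if labels is None and not allow_unlabelled:
        raise ValueError("labels are required")
    return X, None if labels is None else np.asarray(labels)


class ShrinkageLDA:
    """sklearn-style estimator facade over fit_shrinkage_lda/predict_lda."""

    def __init__(self, shrinkage="auto"):
        self.shrinkage = shrinkage
        self.model_ = None

    def fit(self, X, y):
        self.model_ = fit_shrinkage_lda(X, y, shrinkage=self.shrinkage)
        return self

    def predict(self, X):
        labels, _ = predict_lda(self.model_, X)
        return labels

    def decision_values(self, X):
        return lda_scores(self.model_, X)


# ---------------------------------------------------------------------------
# CCA template matching


@dataclass
class CCAReferenceSet:
    """Per-class sinusoidal reference matrices on the epoch's sample grid."""

    references: dict            # class index -> (rows x samples) array
    frequencies: dict = field(default_factory=dict)  # class index -> tuple of Hz
    n_harmonics: int = 2

    def classes(self):
        return sorted(self.references)


def make_cca_references(
    n_samples: int,
    fs: float,
    condition: Condition,
    grid: LineGrid = DEFAULT_GRID,
    n_harmonics: int = 2,
    include_sum: bool = False,
) -> CCAReferenceSet:
    """Build per-class sin/cos references.

    For the pair-coded conditions (top_down, intermediate) each class's
    reference stacks both class frequencies; for bottom_up it uses the
    class's single whole-grid frequency.  Harmonics 1..n_harmonics of every
    frequency are included, plus optionally the pair's sum frequency.
    """
    t = np.arange(n_samples) / fs
    refs, freqmap = {}, {}
    for c in range(1, 7):
        if condition.name == "bottom_up":
            freqs = [condition.bottom_up_freqs[c - 1]]
        else:
            freqs = list(class_frequencies(c, grid))
        base = list(freqs)
        rows = []
        for f in base:
            for h in range(1, n_harmonics + 1):
                rows.append(np.sin(2 * np.pi * h * f * t))
                rows.append(np.cos(2 * np.pi * h * f * t))
        if include_sum and condition.name != "bottom_up":
            fsum = class_sum_frequency(c, grid)
            rows.append(np.sin(2 * np.pi * fsum * t))
            rows.append(np.cos(2 * np.pi * fsum * t))
        refs[c] = np.vstack(rows)
        freqmap[c] = tuple(base)
    return CCAReferenceSet(references=refs, frequencies=freqmap, n_harmonics=n_harmonics)


def cca_max_correlation(X: np.ndarray, Y: np.ndarray) -> float:
    """Largest canonical correlation between two row-variable matrices.

    ``X`` (channels x samples) and ``Y`` (references x samples) are centred
    per row; the correlation is the top singular value of Qx^T Qy where Qx,
    Qy are orthonormal bases of the two row spaces (the whitened
    cross-covariance formulation).
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim != 2 or Y.ndim != 2 or X.shape[1] != Y.shape[1]:
        raise ValueError("X and Y must be 2-D with a common sample axis")
    n = X.shape[1]
    if n < max(X.shape[0], Y.shape[0]):
        raise ValueError("fewer samples than variables")
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    if np.linalg.matrix_rank(Yc) < Y.shape[0]:
        raise ValueError("rank-deficient reference matrix")
    s = np.linalg.svd(_row_space_basis(Xc).T @ _row_space_basis(Yc), compute_uv=False)
    return float(np.clip(s[0], 0.0, 1.0))


def _row_space_basis(Mc: np.ndarray, rtol: float = 1e-10) -> np.ndarray:
    """Orthonormal basis (samples x rank) of a centred row-variable matrix.

    Rank-truncated so that numerically null directions of a degenerate
    epoch cannot contribute spurious correlations.
    """
    U, s, _ = np.linalg.svd(Mc.T, full_matrices=False)
    if s[0] == 0:
        return U[:, :1] * 0.0
    return U[:, s > rtol * s[0]]


def cca_classify(epochs, refs: CCAReferenceSet):
    """Per-trial argmax-correlation classification.

    Returns (labels, correlation matrix trials x classes).  Ties break
    toward the lowest class index and are logged.
    """
    classes = refs.classes()
    if set(classes) != set(range(1, 7)):
        raise ValueError("reference set must cover all six classes")
    if hasattr(epochs, "montage"):
        data = epochs.data
        n_eog = len(epochs.montage.eog_channels)
    else:
        data = np.asarray(epochs)
        n_eog = 0
    n_keep = data.shape[1] - n_eog
    rho = np.empty((data.shape[0], len(classes)))
    # precompute orthonormal bases of the reference row spaces
    qys = {}
    for c in classes:
        Y = refs.references[c]
        Yc = Y - Y.mean(axis=1, keepdims=True)
        if np.linalg.matrix_rank(Yc) < Y.shape[0]:
            raise ValueError(f"rank-deficient reference for class {c}")
        qys[c], _ = np.linalg.qr(Yc.T)
    for i in range(data.shape[0]):
        X = data[i, :n_keep]
        Xc = X - X.mean(axis=1, keepdims=True)
        Qx, _ = np.linalg.qr(Xc.T)
        for j, c in enumerate(classes):
            s = np.linalg.svd(Qx.T @ qys[c], compute_uv=False)
            rho[i, j] = np.clip(s[0], 0.0, 1.0)
    best = rho.argmax(axis=1)
    ties = (rho == rho.max(axis=1, keepdims=True)).sum(axis=1) > 1
    if ties.any():
        logger.debug("CCA ties on %d trials broken toward the lowest class", ties.sum())
    return np.asarray(classes)[best], rho


class CCAClassifier:
    """Estimator facade: training-free CCA decoding of raw epochs.

    ``fit`` is a no-op (templates are fixed sinusoids); ``predict`` expects a
    (trials, channels, samples) array of EEG channels only.
    """

    def __init__(self, refs: CCAReferenceSet):
        self.refs = refs

    def fit(self, X, y=None):
        return self

    def predict(self, X):
        labels, _ = cca_classify(np.asarray(X), self.refs)
        return labels
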