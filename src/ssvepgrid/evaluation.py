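"""Cross-validation, empirical chance, information transfer rate, statistics.

Cross-validation is *chronological*: the 240 trials are split into k=4
contiguous blocks in acquisition order (180 train / 60 test per fold), which
avoids temporal leakage between neighbouring trials.  The empirical chance
level is obtained by rerunning the identical cross-validation with randomly
shuffled labels.  Selection speed is summarized by the Wolpaw information
transfer rate, and condition/model comparisons use one-way repeated-measures
ANOVA (Greenhouse-Geisser corrected), two-tailed paired t-tests, and
Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CVResult",
    "chronological_cv",
    "shuffled_chance",
    "itr_bits_per_min",
    "paired_ttest",
    "fdr_bh",
    "rm_anova_oneway",
    "fold_over_chance",
    "binomial_chance_quantile",
    "binomial_band",
]


@dataclass
class CVResult:
    """Outcome of one chronological cross-validation run."""

    fold_accuracies: np.ndarray
    confusion: np.ndarray                  # classes x classes, rows = true
    predictions: np.ndarray                # per trial (original order)
    fold_of_trial: np.ndarray
    classes: np.ndarray = field(default_factory=lambda: np.arange(1, 7))
    #: out-of-sample decision values (trials x classes) when the classifier
    #: exposes ``decision_values``; used for activation patterns
    decision_values: np.ndarray | None = None

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def overall_accuracy(self) -> float:
        return float(np.trace(self.confusion) / self.confusion.sum())


def chronological_cv(X, labels, chrono_index=None, k: int = 4, classifier=None) -> CVResult:
    """k-fold cross-validation with contiguous chronological folds.

    ``X`` is any array whose first axis indexes trials (a feature matrix or
    raw trials x channels x samples); ``classifier`` follows the
    fit/predict protocol.  When the trial count is not divisible by k, the
    last fold absorbs the remainder.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if classifier is None:
        raise ValueError("a classifier with fit/predict is required")
    if hasattr(X, "matrix"):  # PSDFeatures
        if labels is None:
            labels = X.labels
        if chrono_index is None:
            chrono_index = X.chrono_index
        X = X.matrix
    X = np.asarray(X)
    labels = np.asarray(labels)
    n = X.shape[0]
    chrono_index = np.arange(n) if chrono_index is None else np.asarray(chrono_index)
    order = np.argsort(chrono_index)

    fold_size = n // k
    bounds = [i * fold_size for i in range(k)] + [n]  # last fold absorbs remainder
    classes = np.unique(labels)
    confusion = np.zeros((len(classes), len(classes)), dtype=int)
    predictions = np.empty(n, dtype=labels.dtype)
    fold_of_trial = np.empty(n, dtype=int)
    decision_values = None
    accs = []
    for f in range(k):
        test_pos = order[bounds[f]:bounds[f + 1]]
        train_pos = np.concatenate([order[: bounds[f]], order[bounds[f + 1]:]])
        train_classes = set(np.unique(labels[train_pos]))
        missing = set(classes) - train_classes
        if missing:
            raise ValueError(f"training split of fold {f} is missing class(es) {sorted(missing)}")
        model = classifier.fit(X[train_pos], labels[train_pos])
        pred = np.asarray(model.predict(X[test_pos]))
        predictions[test_pos] = pred
        if hasattr(model, "decision_values"):
            dv = np.asarray(model.decision_values(X[test_pos]))
            if decision_values is None:
                decision_values = np.empty((n, dv.shape[1]))
            decision_values[test_pos] = dv
        fold_of_trial[test_pos] = f
        accs.append(float(np.mean(pred == labels[test_pos])))
        for t, p in zip(labels[test_pos], pred):
            confusion[np.searchsorted(classes, t), np.searchsorted(classes, p)] += 1
    return CVResult(
        fold_accuracies=np.asarray(accs),
        confusion=confusion,
        predictions=predictions,
        fold_of_trial=fold_of_trial,
        classes=classes,
        decision_values=decision_values,
    )


def shuffled_chance(X, labels, chrono_index=None, reps: int = 20, seed=0,
                    k: int = 4, classifier=None):
    """Empirical chance: repeat the CV with randomly shuffled labels.

    Returns (mean over reps, array of per-rep mean accuracies).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if hasattr(X, "matrix"):
        if labels is None:
            labels = X.labels
        if chrono_index is None:
            chrono_index = X.chrono_index
        X = X.matrix
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    means = []
    for _ in range(reps):
        perm = rng.permutation(len(labels))
        res = chronological_cv(X, labels[perm], chrono_index, k=k, classifier=classifier)
        means.append(res.mean_accuracy)
    means = np.asarray(means)
    return float(means.mean()), means


def itr_bits_per_min(P: float, N: int = 6, T: float = 5.0) -> float:
    """Wolpaw information transfer rate in bits/min.

    B = log2 N + P log2 P + (1-P) log2((1-P)/(N-1)) bits per selection, with
    the P in {0, 1} limits taken by continuity, scaled by 60/T selections
    per minute.
    """
    if not 0.0 <= P <= 1.0:
        raise ValueError("P must lie in [0, 1]")
    if N < 2:
        raise ValueError("N must be >= 2")
    if T <= 0:
        raise ValueError("T must be positive")
    B = np.log2(N)
    if P > 0:
        B += P * np.log2(P)
    if P < 1:
        B += (1 - P) * np.log2((1 - P) / (N - 1))
    return float(B * 60.0 / T)


def paired_ttest(a, b):
    """Two-tailed paired t-test; returns (t, df, p).

    Zero-variance nonzero differences give t = +/-inf and p = 0 by
    convention; identically zero differences give t = 0, p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("a and b must be equal-length 1-D arrays with n >= 2")
    d = a - b
    df = len(d) - 1
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d.mean(), 0.0):
            return 0.0, df, 1.0
        return float(np.sign(d.mean()) * np.inf), df, 0.0
    t, p = stats.ttest_rel(a, b)
    return float(t), df, float(p)


def fdr_bh(pvalues, q: float = 0.2) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection flags at FDR level q."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def rm_anova_oneway(matrix):
    """One-way repeated-measures ANOVA with Greenhouse-Geisser correction.

    ``matrix`` is subjects x conditions, complete (no missing cells).
    Returns (F, df1, df2, epsilon, p) where the p-value uses
    epsilon-corrected degrees of freedom whenever epsilon < 1.
    """
    Y = np.asarray(matrix, dtype=float)
    if Y.ndim != 2 or Y.shape[0] < 2 or Y.shape[1] < 2:
        raise ValueError("matrix must be subjects x conditions with >= 2 of each")
    if not np.all(np.isfinite(Y)):
        raise ValueError("missing or non-finite cells are not supported")
    n, kc = Y.shape
    grand = Y.mean()
    subj = Y.mean(axis=1, keepdims=True)
    cond = Y.mean(axis=0, keepdims=True)
    ss_cond = n * ((cond - grand) ** 2).sum()
    ss_err = ((Y - subj - cond + grand) ** 2).sum()
    df1, df2 = kc - 1, (n - 1) * (kc - 1)

    # Greenhouse-Geisser epsilon from the double-centred condition covariance
    S = np.cov(Y, rowvar=False, ddof=1)
    C = np.eye(kc) - np.ones((kc, kc)) / kc
    Sc = C @ S @ C
    tr = np.trace(Sc)
    denom = df1 * np.trace(Sc @ Sc)
    eps = 1.0 if denom <= 0 else float(np.clip(tr**2 / denom, 1.0 / df1, 1.0))

    if ss_cond == 0:
        return 0.0, df1, df2, eps, 1.0
    if ss_err == 0:
        return float(np.inf), df1, df2, eps, 0.0
    F = (ss_cond / df1) / (ss_err / df2)
    p = float(stats.f.sf(F, df1 * eps, df2 * eps))
    return float(F), df1, df2, eps, p


def fold_over_chance(accuracy: float, chance: float) -> float:
    """Accuracy expressed as a multiple of the chance level."""
    if chance <= 0:
        raise ValueError("chance must be positive")
    return accuracy / chance


def binomial_chance_quantile(n_trials: int, n_classes: int = 6, q: float = 0.95) -> float:
    """Upper q-quantile of guessing accuracy for n_trials balanced trials."""
    return float(stats.binom.ppf(q, n_trials, 1.0 / n_classes) / n_trials)


def binomial_band(n_trials: int, n_classes: int = 6, alpha: float = 0.05):
    """Central (1-alpha) band of guessing accuracy (exact binomial quantiles)."""
    p = 1.0 / n_classes
    lo = stats.binom.ppf(alpha / 2, n_trials, p) / n_trials
    hi = stats.binom.ppf(1 - alpha / 2, n_trials, p) / n_trials
    return float(lo), float(hi)
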