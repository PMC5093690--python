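"""Activation patterns: forward-model interpretation of linear decoder weights.

The weight vector of a linear classifier mixes signal and noise directions
and cannot be read as a scalp map.  The activation pattern resolves this:
for uncorrelated noise it is proportional to the covariance between the
classifier's continuous output and each feature.  To make patterns
comparable across conditions this module uses the Pearson *correlation*
between the trial-wise discriminant outputs and each spectral feature.  The
six per-class discriminants are combined per feature by the mean absolute
correlation, then averaged across frequency bins to yield one value per
channel — a single scalp map per condition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = ["ActivationPattern", "activation_pattern", "pattern_extremum"]

logger = logging.getLogger(__name__)


@dataclass
class ActivationPattern:
    """Per-channel pattern values plus the retained raw correlations."""

    values: np.ndarray          # per channel, mean |corr| over bins
    channel_names: tuple
    raw: np.ndarray             # channels x bins, mean |corr| over discriminants
    signed: np.ndarray          # channels x bins x discriminants, signed Pearson r
    bin_freqs: np.ndarray | None = None
    condition: str | None = None


def activation_pattern(features, outputs, condition=None) -> ActivationPattern:
    """Correlate trial-wise classifier outputs with every spectral feature.

    Parameters
    ----------
    features
        A PSDFeatures object (or matrix with channel/bin structure supplied
        through it).
    outputs
        (trials,) or (trials, n_discriminants) continuous classifier
        outputs, e.g. the per-class LDA decision values.
    """
    X = features.matrix
    out = np.asarray(outputs, dtype=float)
    if out.ndim == 1:
        out = out[:, None]
    if out.shape[0] != X.shape[0]:
        raise ValueError("one output row per trial is required")
    if X.shape[0] < 3:
        raise ValueError("need at least 3 trials to correlate")
    out_sd = out.std(axis=0)
    if np.any(out_sd == 0):
        raise ValueError("classifier output has zero variance")

    Xc = X - X.mean(axis=0)
    Oc = out - out.mean(axis=0)
    x_sd = Xc.std(axis=0)
    zero_feats = x_sd == 0
    if zero_feats.any():
        logger.warning(
            "%d zero-variance features; their correlations set to 0", zero_feats.sum()
        )
    denom = np.outer(np.where(zero_feats, 1.0, x_sd), out_sd) * X.shape[0]
    corr = (Xc.T @ Oc) / denom          # features x discriminants
    corr[zero_feats] = 0.0
    corr = np.clip(corr, -1.0, 1.0)

    n_ch, n_bins = features.n_channels, features.n_bins
    signed = corr.reshape(n_ch, n_bins, -1)
    raw = np.abs(signed).mean(axis=2)   # combine discriminants
    values = raw.mean(axis=1)           # average across frequency bins
    return ActivationPattern(
        values=values,
        channel_names=tuple(features.channel_names),
        raw=raw,
        signed=signed,
        bin_freqs=np.asarray(features.bin_freqs),
        condition=condition if condition is not None else features.condition,
    )


def pattern_extremum(pattern: ActivationPattern):
    """Maximum absolute channel value and its channel name."""
    if len(pattern.values) == 0:
        raise ValueError("empty pattern")
    i = int(np.abs(pattern.values).argmax())
    return float(np.abs(pattern.values[i])), pattern.channel_names[i]


def pattern_to_csv(pattern: ActivationPattern, path) -> None:
    """Write (channel, value) rows."""
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["channel", "value"])
        for ch, v in zip(pattern.channel_names, pattern.values):
            w.writerow([ch, f"{v:.6f}"])


def plot_scalp_map(pattern: ActivationPattern, montage, ax=None):
    """Render the pattern on the 2-D montage (cosmetic; values are the contract)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    xs, ys, vs = [], [], []
    for ch, v in zip(pattern.channel_names, pattern.values):
        if ch in montage.positions:
            x, y = montage.positions[ch]
            xs.append(x), ys.append(y), vs.append(v)
    sc = ax.tricontourf(xs, ys, vs, levels=12, cmap="viridis")
    ax.scatter(xs, ys, c="k", s=6)
    ax.set_aspect("equal")
    ax.set_axis_off()
    return sc
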