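"""FFT power-spectral-density features on the 5-13.5 Hz grid.

Each trial and channel is reduced to log power at 18 nominal bins from 5 Hz
to 13.5 Hz in 0.5 Hz steps — a band that covers the six line frequencies,
their second harmonics up to 13 Hz, and the sum (intermodulation)
frequencies of the letter pairs, whose maximum is exactly 13.5 Hz.

A 5 s epoch has a native FFT grid of 0.2 Hz on which the half-integer bins
(5.5, 6.5, 7.5 Hz) do not fall; epochs are therefore mean-removed and
zero-padded to a 0.1 Hz grid and the exact nominal bins are read off, with
no interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PSDFeatures", "psd_features", "select_channels", "OCCIPITAL_PRESET", "EOG_PRESET"]

#: log-power floor: power below this is clipped (features >= log10(EPS))
EPS = 1e-12

DEFAULT_BAND = (5.0, 13.5, 0.5)
OCCIPITAL_PRESET = ("Oz", "O1", "O2")
EOG_PRESET = ("vEOG", "hEOG")

#: zero-padding target resolution in Hz
_GRID_HZ = 0.1


@dataclass
class PSDFeatures:
    """Trial-wise spectral log-power features.

    ``matrix`` has shape (trials, channels * bins); column order is
    channel-major (all bins of channel 0, then channel 1, ...).
    """

    matrix: np.ndarray
    bin_freqs: np.ndarray
    channel_names: tuple
    labels: np.ndarray | None = None
    chrono_index: np.ndarray | None = None
    condition: str | None = None
    feature_index: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.feature_index:
            self.feature_index = {
                (ch, float(f)): i * len(self.bin_freqs) + j
                for i, ch in enumerate(self.channel_names)
                for j, f in enumerate(self.bin_freqs)
            }
        expected = len(self.channel_names) * len(self.bin_freqs)
        if self.matrix.shape[1] != expected:
            raise ValueError(
                f"matrix has {self.matrix.shape[1]} columns, expected {expected}"
            )

    @property
    def n_trials(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    @property
    def n_bins(self) -> int:
        return len(self.bin_freqs)

    def column(self, channel: str, freq: float) -> int:
        return self.feature_index[(channel, float(freq))]

    def as_channel_bin_array(self) -> np.ndarray:
        """Reshape to (trials, channels, bins)."""
        return self.matrix.reshape(self.n_trials, self.n_channels, self.n_bins)

    def header(self) -> list:
        """CSV header labels ``<channel>@<freq>Hz`` in column order."""
        return [
            f"{ch}@{f:g}Hz" for ch in self.channel_names for f in self.bin_freqs
        ]


def spectrum_power(x: np.ndarray, n_fft: int | None = None) -> np.ndarray:
    """Two-sided per-bin power of a 1-D signal on the (padded) FFT grid.

    Normalized so the sum over the full FFT grid equals the mean-square of
    the original samples (a Parseval identity); zero-padding spreads no extra
    power.
    """
    x = np.asarray(x, dtype=float)
    n_sig = x.shape[-1]
    n_fft = n_fft or n_sig
    X = np.fft.fft(x, n=n_fft, axis=-1)
    return np.abs(X) ** 2 / (n_fft * n_sig)


def psd_features(epochs, band=DEFAULT_BAND, window: str = "rect") -> PSDFeatures:
    """Compute the trial x (channel*bin) log-power feature matrix.

    Parameters
    ----------
    epochs
        An :class:`~ssvepgrid.epochs.EpochSet`.
    band
        (lo, hi, step) in Hz; default the 5-13.5 Hz grid in 0.5 Hz steps.
    window
        "rect" (default) or "hann" taper applied before the FFT.
    """
    lo, hi, step = band
    if epochs.n_trials == 0:
        raise ValueError("empty epoch set")
    if not (0 < lo <= hi < epochs.fs / 2):
        raise ValueError(f"band {band} outside (0, Nyquist={epochs.fs / 2}) Hz")
    bad = np.argwhere(~np.isfinite(epochs.data))
    if len(bad):
        tr, ch, _ = bad[0]
        raise ValueError(
            f"non-finite sample in trial {tr}, channel {epochs.channel_names[ch]}"
        )

    bin_freqs = np.round(np.arange(lo, hi + step / 2, step), 6)
    n_sig = epochs.n_samples
    # zero-pad to the 0.1 Hz grid (next multiple of fs/0.1 samples)
    n_fft = max(n_sig, int(round(epochs.fs / _GRID_HZ)))
    grid_hz = epochs.fs / n_fft
    idx = np.round(bin_freqs / grid_hz).astype(int)
    if not np.allclose(idx * grid_hz, bin_freqs, atol=1e-9):
        raise ValueError(f"bins {bin_freqs} do not fall on the padded FFT grid")

    x = epochs.data - epochs.data.mean(axis=2, keepdims=True)
    if window == "hann":
        x = x * np.hanning(n_sig)
    elif window != "rect":
        raise ValueError("window must be 'rect' or 'hann'")
    # one-sided power at the nominal bins
    power = 2.0 * spectrum_power(x, n_fft=n_fft)[..., idx]
    feats = np.log10(np.maximum(power, EPS))

    matrix = feats.reshape(epochs.n_trials, -1)
    return PSDFeatures(
        matrix=matrix,
        bin_freqs=bin_freqs,
        channel_names=tuple(epochs.channel_names),
        labels=None if epochs.labels is None else epochs.labels.copy(),
        chrono_index=None if epochs.chrono_index is None else epochs.chrono_index.copy(),
        condition=epochs.condition,
    )


def select_channels(features: PSDFeatures, subset) -> PSDFeatures:
    """Restrict features to a channel subset (e.g. occipital or EOG presets)."""
    subset = tuple(subset)
    unknown = [ch for ch in subset if ch not in features.channel_names]
    if unknown:
        raise KeyError(
            f"unknown channels {unknown}; valid: {list(features.channel_names)}"
        )
    cols = [
        features.column(ch, f) for ch in subset for f in features.bin_freqs
    ]
    return PSDFeatures(
        matrix=features.matrix[:, cols],
        bin_freqs=features.bin_freqs.copy(),
        channel_names=subset,
        labels=features.labels,
        chrono_index=features.chrono_index,
        condition=features.condition,
    )
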