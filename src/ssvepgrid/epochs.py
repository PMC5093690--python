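"""The epoch container: trials x channels x samples with sidecar metadata."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .paradigm import Montage, default_montage

__all__ = ["EpochSet"]


@dataclass
class EpochSet:
    """A set of stimulation epochs.

    Parameters
    ----------
    data
        Array of shape (trials, channels, samples), microvolts.
    fs
        Sampling rate in Hz (500 by default throughout the package).
    labels
        Integer class labels in 1..6, one per trial.
    condition
        Condition name ("top_down", "intermediate" or "bottom_up").
    montage
        Electrode montage; ``montage.channel_names`` must match axis 1.
    chrono_index
        Acquisition order of the trials: a permutation of 0..trials-1.
        Trial i was recorded at position ``chrono_index[i]``.
    info
        Free-form provenance (generator config, seed, ground-truth
        topographies); not required for analysis.
    """

    data: np.ndarray
    fs: float
    labels: np.ndarray
    condition: str
    montage: Montage = field(default_factory=default_montage)
    chrono_index: np.ndarray | None = None
    info: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != (self.n_trials,):
            raise ValueError("labels must have one entry per trial")
        if self.data.shape[1] != len(self.channel_names):
            raise ValueError(
                f"data has {self.data.shape[1]} channels but montage names "
                f"{len(self.channel_names)}"
            )
        if self.chrono_index is None:
            self.chrono_index = np.arange(self.n_trials)
        self.chrono_index = np.asarray(self.chrono_index, dtype=int)
        if sorted(self.chrono_index) != list(range(self.n_trials)):
            raise ValueError("chrono_index must be a permutation of 0..trials-1")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def channel_names(self) -> tuple:
        return self.montage.channel_names

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"unknown channel {name!r}; valid: {list(self.channel_names)}"
            ) from None

    def in_chronological_order(self) -> "EpochSet":
        """Return a copy with trials sorted by acquisition order."""
        order = np.argsort(self.chrono_index)
        return EpochSet(
            data=self.data[order],
            fs=self.fs,
            labels=self.labels[order],
            condition=self.condition,
            montage=self.montage,
            chrono_index=np.arange(self.n_trials),
            info=dict(self.info),
        )
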