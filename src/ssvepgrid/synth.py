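"""Synthetic grid-paradigm SSVEP epochs and coupled-source ground truth.

The generator emulates the statistical structure the decoding chain assumes:
steady-state sinusoidal responses at the six line frequencies projected onto
the scalp through occipitally centred Gaussian topographies, 1/f background
noise, a spontaneous alpha rhythm, optional intermodulation (sum-frequency)
components, and class-independent ocular artifact channels.  Condition
semantics follow the paradigm: in the top-down condition every line is
physically present at full amplitude and only an attentional gain on the
class's row/column pair carries information; the intermediate condition dims
task-irrelevant lines to 1/10 amplitude; the bottom-up condition flickers the
whole grid at one class-specific frequency.

A second generator produces a two-source system (a "frontal" and an
"occipital" latent source) coupled through a known multivariate
autoregression, giving ground truth for the directed-connectivity stage.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field

import numpy as np

from .epochs import EpochSet
from .paradigm import (
    DEFAULT_GRID,
    Condition,
    LineGrid,
    Montage,
    class_frequencies,
    class_sum_frequency,
    default_montage,
    letter_class,
)

__all__ = [
    "SynthConfig",
    "CoupledSourceTruth",
    "pink_noise",
    "simulate_epochs",
    "simulate_coupled_sources",
]

_CONDITION_CODE = {"top_down": 0, "intermediate": 1, "bottom_up": 2}


@dataclass(frozen=True)
class SynthConfig:
    """Generator parameters (amplitudes in microvolts).

    ``attention_gain`` is the multiplicative gain kappa on the attended
    row/column pair: attended lines have amplitude ``base_amp * (1 + g)``
    where the realized gain g is drawn per trial as kappa times a
    unit-mean Gamma variate with coefficient of variation ``gain_jitter``
    (0 = a deterministic gain; 1 = exponential-like attentional
    fluctuation).  The fluctuation is shared by both attended lines of a
    trial, so it acts as common-mode variability a spatial decoder cannot
    average away — the main reason single-trial top-down decoding is hard.
    With ``attention_gain=0`` the top-down condition carries no class
    information at all.
    """

    base_amp: float = 1.0
    attention_gain: float = 0.4
    gain_jitter: float = 1.0
    intermod_amp: float = 0.1
    noise_pink_amp: float = 4.5
    alpha_amp: float = 2.0
    alpha_freq: float = 10.0
    topo_width: float = 0.25
    topo_jitter: float = 0.05
    eog_amp: float = 10.0
    seed: int = 0
    trials_per_class: int = 40
    duration: float = 5.0
    fs: float = 500.0

    def __post_init__(self):
        amps = (self.base_amp, self.attention_gain, self.gain_jitter,
                self.intermod_amp, self.noise_pink_amp, self.alpha_amp, self.eog_amp)
        if any(not math.isfinite(a) or a < 0 for a in amps):
            raise ValueError("all amplitudes must be finite and nonnegative")
        if self.fs <= 0 or self.duration <= 0:
            raise ValueError("fs and duration must be positive")
        if self.topo_width <= 0:
            raise ValueError("topo_width must be positive")
        if self.trials_per_class < 1:
            raise ValueError("trials_per_class must be >= 1")

    @property
    def n_samples(self) -> int:
        return round(self.duration * self.fs)


def pink_noise(n_samples: int, fs: float, rng) -> np.ndarray:
    """Zero-mean unit-variance noise with PSD proportional to 1/f.

    The 1/f slope holds over [1 Hz, fs/2]; below 1 Hz the spectrum is
    flattened so the variance stays finite.  ``rng`` may be a Generator or an
    integer seed.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    scale = 1.0 / np.sqrt(np.maximum(freqs, 1.0))
    scale[0] = 0.0  # no DC
    spec = scale * (rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs)))
    x = np.fft.irfft(spec, n=n_samples)
    x -= x.mean()
    sd = x.std()
    if sd > 0:
        x /= sd
    return x


def _gaussian_topography(montage: Montage, center, width: float) -> np.ndarray:
    """Gaussian spatial profile over the 30 EEG channels; EOG rows are zero."""
    pos = np.array([montage.positions[ch] for ch in montage.eeg_channels])
    d2 = ((pos - np.asarray(center)) ** 2).sum(axis=1)
    g = np.exp(-d2 / (2.0 * width**2))
    return np.concatenate([g, np.zeros(len(montage.eog_channels))])


def _trial_sequence(n_classes: int, trials_per_class: int, rng) -> np.ndarray:
    """Chronological label sequence: randomized blocks, one trial per class."""
    blocks = [rng.permutation(n_classes) + 1 for _ in range(trials_per_class)]
    return np.concatenate(blocks)


def simulate_epochs(
    cfg: SynthConfig,
    condition: Condition,
    grid: LineGrid = DEFAULT_GRID,
    montage: Montage | None = None,
) -> EpochSet:
    """Simulate one condition's epoch set (balanced, chronologically ordered).

    Trials are generated in acquisition order as randomized blocks containing
    one trial of each class, so every contiguous quarter of the session is
    class-balanced; ``chrono_index`` records the order for chronological
    cross-validation.
    """
    montage = montage or default_montage()
    rng = np.random.default_rng([int(cfg.seed), _CONDITION_CODE.get(condition.name, 9)])
    n_ch = len(montage.channel_names)
    n_eog = len(montage.eog_channels)
    n = cfg.n_samples
    t = np.arange(n) / cfg.fs

    # per-line Gaussian topographies, centres jittered around Oz
    oz = np.asarray(montage.positions["Oz"])
    lines = list(grid.frequencies)
    centers = {
        l: oz + cfg.topo_jitter * rng.standard_normal(2) for l in lines
    }
    topo = {l: _gaussian_topography(montage, centers[l], cfg.topo_width) for l in lines}
    # broad posterior topography for the alpha rhythm
    alpha_topo = _gaussian_topography(montage, (0.0, -0.25), 2.0 * cfg.topo_width)

    labels = _trial_sequence(6, cfg.trials_per_class, rng)
    n_trials = len(labels)
    data = np.empty((n_trials, n_ch, n))

    for i, lab in enumerate(labels):
        letter = letter_class(int(lab))
        attended = {letter.row_line, letter.col_line}
        x = np.zeros((n_ch, n))

        if condition.name == "bottom_up":
            # the whole grid flickers as one object: one common frequency and
            # phase, so the six line responses superpose coherently
            f = condition.bottom_up_freqs[int(lab) - 1]
            phase = rng.uniform(0, 2 * np.pi)
            for l in lines:
                x += np.outer(topo[l], cfg.base_amp * np.sin(2 * np.pi * f * t + phase))
        else:
            # one attentional-gain draw per trial, common to both attended lines
            if cfg.gain_jitter > 0 and cfg.attention_gain > 0:
                shape = 1.0 / cfg.gain_jitter**2
                gain = cfg.attention_gain * rng.gamma(shape, 1.0 / shape)
            else:
                gain = cfg.attention_gain
            for l in lines:
                amp = cfg.base_amp * (
                    (1.0 + gain) if l in attended else condition.irrelevant_scale
                )
                phase = rng.uniform(0, 2 * np.pi)
                f = grid.line_frequency(l)
                x += np.outer(topo[l], amp * np.sin(2 * np.pi * f * t + phase))
            if cfg.intermod_amp > 0:
                f_im = class_sum_frequency(letter, grid)
                im_topo = 0.5 * (topo[letter.row_line] + topo[letter.col_line])
                phase = rng.uniform(0, 2 * np.pi)
                x += np.outer(im_topo, cfg.intermod_amp * np.sin(2 * np.pi * f_im * t + phase))

        # spontaneous alpha rhythm, class-independent
        if cfg.alpha_amp > 0:
            phase = rng.uniform(0, 2 * np.pi)
            x += np.outer(
                alpha_topo, cfg.alpha_amp * np.sin(2 * np.pi * cfg.alpha_freq * t + phase)
            )
        # 1/f background on EEG channels
        for c in range(n_ch - n_eog):
            x[c] += cfg.noise_pink_amp * pink_noise(n, cfg.fs, rng)
        # ocular derivations: class-independent artifact noise only
        for c in range(n_ch - n_eog, n_ch):
            x[c] = cfg.eog_amp * pink_noise(n, cfg.fs, rng)
        data[i] = x

    return EpochSet(
        data=data,
        fs=cfg.fs,
        labels=labels,
        condition=condition.name,
        montage=montage,
        chrono_index=np.arange(n_trials),
        info={
            "config": asdict(cfg),
            "line_topographies": {l: topo[l].copy() for l in lines},
            "topography_centers": {l: centers[l].copy() for l in lines},
        },
    )


# ---------------------------------------------------------------------------
# coupled frontal/occipital sources for the connectivity stage


def _ar2_poly(f0: float, fs: float, radius: float):
    """AR(2) coefficients of a damped oscillator resonant at f0."""
    w = 2.0 * np.pi * f0 / fs
    return 2.0 * radius * np.cos(w), -radius**2


def companion_spectral_radius(coeffs: np.ndarray) -> float:
    """Spectral radius of the companion matrix of an MVAR coefficient stack."""
    p, m, _ = coeffs.shape
    comp = np.zeros((m * p, m * p))
    comp[:m, :] = np.concatenate(list(coeffs), axis=1)
    if p > 1:
        comp[m:, :-m] = np.eye(m * (p - 1))
    return float(np.abs(np.linalg.eigvals(comp)).max())


@dataclass(frozen=True)
class CoupledSourceTruth:
    """Known 2-channel AR system: source 0 is frontal (F), source 1 occipital (O)."""

    coeffs: np.ndarray  # (order, 2, 2)
    noise_cov: np.ndarray = field(default_factory=lambda: np.eye(2))
    coupling: str = "F->O"  # one of {"F->O", "O->F", "none"}

    def __post_init__(self):
        object.__setattr__(self, "coeffs", np.asarray(self.coeffs, dtype=float))
        object.__setattr__(self, "noise_cov", np.asarray(self.noise_cov, dtype=float))
        if self.coupling not in ("F->O", "O->F", "none"):
            raise ValueError("coupling must be 'F->O', 'O->F' or 'none'")
        rho = companion_spectral_radius(self.coeffs)
        if rho >= 1.0:
            raise ValueError(f"unstable AR system: companion spectral radius {rho:.4f} >= 1")

    @classmethod
    def default(
        cls,
        coupling: str = "F->O",
        strength: float = 0.4,
        fs: float = 500.0,
        f_frontal: float = 6.0,
        f_occipital: float = 7.0,
        radius: float = 0.95,
        coupling_lag: int = 8,
    ) -> "CoupledSourceTruth":
        """Two theta-band oscillators with unidirectional delayed coupling.

        The coupling acts at ``coupling_lag`` samples (16 ms at 500 Hz, a
        plausible cortico-cortical conduction delay).  A clear transmission
        delay is also what makes the causal direction identifiable and its
        reversal detectable on time-reversed data; instantaneous-like (lag-1)
        coupling between two sharp resonators yields nearly time-symmetric
        cross-correlation from which no finite-order model can recover the
        flip.
        """
        a1f, a2f = _ar2_poly(f_frontal, fs, radius)
        a1o, a2o = _ar2_poly(f_occipital, fs, radius)
        p = max(2, int(coupling_lag))
        A = np.zeros((p, 2, 2))
        A[0] = np.diag([a1f, a1o])
        A[1] += np.diag([a2f, a2o])
        if coupling == "F->O":
            A[coupling_lag - 1][1, 0] += strength
        elif coupling == "O->F":
            A[coupling_lag - 1][0, 1] += strength
        return cls(coeffs=A, coupling=coupling)


def simulate_ar(truth: CoupledSourceTruth, n_samples: int, rng, burn_in: int = 1000) -> np.ndarray:
    """Simulate the latent AR system; returns (2, n_samples)."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    p, m, _ = truth.coeffs.shape
    total = n_samples + burn_in
    chol = np.linalg.cholesky(truth.noise_cov)
    eps = chol @ rng.standard_normal((m, total))
    x = np.zeros((m, total))
    for n in range(p, total):
        acc = eps[:, n].copy()
        for k in range(p):
            acc += truth.coeffs[k] @ x[:, n - 1 - k]
        x[:, n] = acc
    return x[:, burn_in:]


def simulate_coupled_sources(
    cfg: SynthConfig,
    truth: CoupledSourceTruth | None = None,
    grid: LineGrid = DEFAULT_GRID,
    montage: Montage | None = None,
    n_trials: int = 40,
):
    """Project coupled latent sources onto the scalp.

    Returns ``(epochs, sources)`` where ``sources`` is the (2, total samples)
    latent time series (frontal first) whose trials concatenate to the epoch
    set.  Channel data are the two sources through frontal/occipital Gaussian
    topographies plus 1/f sensor noise; ocular channels carry noise only.
    """
    truth = truth or CoupledSourceTruth.default(fs=cfg.fs)
    montage = montage or default_montage()
    rng = np.random.default_rng([int(cfg.seed), 7])
    n = cfg.n_samples
    total = n * n_trials
    sources = simulate_ar(truth, total, rng)
    sources = sources / sources.std(axis=1, keepdims=True)

    frontal = _gaussian_topography(montage, (0.0, 0.45), cfg.topo_width)
    occipital = _gaussian_topography(montage, montage.positions["Oz"], cfg.topo_width)
    T = np.stack([frontal, occipital], axis=1)  # channels x 2

    n_ch = len(montage.channel_names)
    n_eog = len(montage.eog_channels)
    data = np.empty((n_trials, n_ch, n))
    for i in range(n_trials):
        x = cfg.base_amp * (T @ sources[:, i * n : (i + 1) * n])
        for c in range(n_ch - n_eog):
            x[c] += cfg.noise_pink_amp * pink_noise(n, cfg.fs, rng)
        for c in range(n_ch - n_eog, n_ch):
            x[c] = cfg.eog_amp * pink_noise(n, cfg.fs, rng)
        data[i] = x

    epochs = EpochSet(
        data=data,
        fs=cfg.fs,
        labels=np.ones(n_trials, dtype=int),
        condition="coupled_sources",
        montage=montage,
        chrono_index=np.arange(n_trials),
        info={
            "config": asdict(cfg),
            "coupling": truth.coupling,
            "ar_coeffs": truth.coeffs.copy(),
            "frontal_topography": frontal,
            "occipital_topography": occipital,
        },
    )
    return epochs, sources
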