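"""Stimulus paradigm: the flickering line grid, letter classes, conditions, montage.

The stimulus is a 6 cm x 6 cm grid of three horizontal (R1-R3) and three
vertical (C1-C3) lines, each flickering at its own frequency between 5 and
7.5 Hz.  A letter-like symbol is encoded by covertly attending to one
row/column pair, so each of the six classes is a *frequency pair*, and each
single line frequency is shared by exactly two classes.  That sharing is the
structural reason single-frequency template decoders are ambiguous for the
top-down paradigm: only the pair identifies the class.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace

import yaml

__all__ = [
    "LineGrid",
    "LetterClass",
    "Condition",
    "Montage",
    "DEFAULT_GRID",
    "LETTER_CLASSES",
    "default_montage",
    "class_frequencies",
    "class_sum_frequency",
    "grid_to_yaml",
    "grid_from_yaml",
    "condition_to_yaml",
    "condition_from_yaml",
]

ROW_LINES = ("R1", "R2", "R3")
COL_LINES = ("C1", "C2", "C3")

#: Default line frequencies in Hz.
DEFAULT_ROW_FREQS = {"R1": 5.0, "R2": 6.0, "R3": 7.0}
DEFAULT_COL_FREQS = {"C1": 5.5, "C2": 6.5, "C3": 7.5}


@dataclass(frozen=True)
class LineGrid:
    """Geometry and flicker frequencies of the grid-shaped line array."""

    row_freqs: dict = field(default_factory=lambda: dict(DEFAULT_ROW_FREQS))
    col_freqs: dict = field(default_factory=lambda: dict(DEFAULT_COL_FREQS))
    line_width_mm: float = 6.0
    spacing_cm: float = 1.0
    size_cm: float = 6.0

    def __post_init__(self):
        if set(self.row_freqs) != set(ROW_LINES) or set(self.col_freqs) != set(COL_LINES):
            raise ValueError("grid must define frequencies for R1-R3 and C1-C3")
        freqs = list(self.row_freqs.values()) + list(self.col_freqs.values())
        if len(set(freqs)) != 6:
            raise ValueError("the six line frequencies must be distinct")
        if min(freqs) < 5.0 or max(freqs) > 7.5:
            raise ValueError("line frequencies must lie in [5, 7.5] Hz")
        if self.line_width_mm <= 0 or self.spacing_cm <= 0 or self.size_cm <= 0:
            raise ValueError("grid dimensions must be positive")

    def line_frequency(self, line: str) -> float:
        if line in self.row_freqs:
            return self.row_freqs[line]
        if line in self.col_freqs:
            return self.col_freqs[line]
        raise KeyError(f"unknown line {line!r}")

    @property
    def frequencies(self) -> dict:
        return {**self.row_freqs, **self.col_freqs}


DEFAULT_GRID = LineGrid()


@dataclass(frozen=True)
class LetterClass:
    """One of the six letter-shaped stimuli (Korean phonemes)."""

    index: int
    symbol: str  # Unicode glyph
    name: str    # transliterated ASCII name, encoding-safe
    row_line: str
    col_line: str


#: The six classes: (glyph, transliteration, row line, column line).
LETTER_CLASSES = (
    LetterClass(1, "┐", "giyeok", "R1", "C3"),
    LetterClass(2, "└", "nieun", "R3", "C1"),
    LetterClass(3, "⊥", "o", "R3", "C2"),
    LetterClass(4, "⊤", "u", "R1", "C2"),
    LetterClass(5, "⊢", "a", "R2", "C1"),
    LetterClass(6, "⊣", "eo", "R2", "C3"),
)

N_CLASSES = len(LETTER_CLASSES)


def letter_class(index: int) -> LetterClass:
    """Return the letter class with 1-based ``index``."""
    if not 1 <= int(index) <= 6:
        raise ValueError(f"class index must be in 1..6, got {index}")
    return LETTER_CLASSES[int(index) - 1]


def class_frequencies(letter: LetterClass | int, grid: LineGrid = DEFAULT_GRID):
    """Frequency pair (row_freq, col_freq) in Hz encoding one letter class."""
    if isinstance(letter, int):
        letter = letter_class(letter)
    return (grid.line_frequency(letter.row_line), grid.line_frequency(letter.col_line))


def class_sum_frequency(letter: LetterClass | int, grid: LineGrid = DEFAULT_GRID) -> float:
    """Sum of the two class frequencies (the intermodulation frequency), Hz."""
    fr, fc = class_frequencies(letter, grid)
    return fr + fc


CONDITION_NAMES = ("top_down", "intermediate", "bottom_up")

#: Whole-grid flicker frequencies per class for the bottom-up condition, Hz.
DEFAULT_BOTTOM_UP_FREQS = (5.0, 5.5, 6.0, 6.5, 7.0, 7.5)


@dataclass(frozen=True)
class Condition:
    """Experimental condition semantics.

    top_down
        All six lines flicker at full luminance; only covert attention to the
        class's row/column pair carries class information.
    intermediate
        Task-irrelevant lines are dimmed to 1/10 luminance.
    bottom_up
        The whole grid flickers at one class-specific frequency (classical
        single-frequency paradigm).
    """

    name: str
    irrelevant_scale: float = 1.0
    bottom_up_freqs: tuple = DEFAULT_BOTTOM_UP_FREQS

    def __post_init__(self):
        if self.name not in CONDITION_NAMES:
            raise ValueError(f"condition must be one of {CONDITION_NAMES}, got {self.name!r}")
        if not 0.0 <= self.irrelevant_scale <= 1.0:
            raise ValueError("irrelevant_scale must lie in [0, 1]")
        if self.name == "bottom_up" and len(self.bottom_up_freqs) != N_CLASSES:
            raise ValueError("bottom_up_freqs needs one frequency per class")


def condition(name: str) -> Condition:
    """Construct a condition with its default semantics."""
    scales = {"top_down": 1.0, "intermediate": 0.1, "bottom_up": 1.0}
    if name not in scales:
        raise ValueError(f"condition must be one of {CONDITION_NAMES}, got {name!r}")
    return Condition(name=name, irrelevant_scale=scales[name])


# 2-D unit-disc electrode positions (x = right, y = anterior), static table of
# standard 10-10 projected coordinates; used for scalp maps and the Gaussian
# forward model only.
_EEG_POSITIONS = {
    "Fp1": (-0.1738, +0.4954), "Fp2": (+0.1743, +0.4952),
    "F7": (-0.4655, +0.2814), "F3": (-0.2291, +0.2422), "Fz": (+0.0012, +0.2298),
    "F4": (+0.2358, +0.2470), "F8": (+0.4651, +0.2829),
    "FC5": (-0.3936, +0.0950), "FC1": (-0.1244, +0.0950),
    "FC2": (+0.1283, +0.0975), "FC6": (+0.3956, +0.0991),
    "T7": (-0.5252, -0.1000), "C3": (-0.2510, -0.0447), "Cz": (+0.0013, -0.0290),
    "C4": (+0.2573, -0.0418), "T8": (+0.5267, -0.0930),
    "CP5": (-0.3426, -0.2004), "CP1": (-0.1099, -0.1463),
    "CP2": (+0.1187, -0.1456), "CP6": (+0.3493, -0.1933),
    "P7": (-0.3565, -0.3615), "P3": (-0.1845, -0.2743), "Pz": (+0.0010, -0.2471),
    "P4": (+0.1913, -0.2700), "P8": (+0.3591, -0.3591),
    "PO9": (-0.2919, -0.5211), "O1": (-0.1204, -0.4604), "Oz": (+0.0004, -0.4596),
    "O2": (+0.1224, -0.4599), "PO10": (+0.2921, -0.5211),
}

EOG_CHANNELS = ("vEOG", "hEOG")  # Fp1-minus-suborbital and F7-minus-F8 derivations


@dataclass(frozen=True)
class Montage:
    """30 EEG channels of the 10-10 system plus the two EOG derivations."""

    eeg_channels: tuple = tuple(_EEG_POSITIONS)
    eog_channels: tuple = EOG_CHANNELS
    positions: dict = field(default_factory=lambda: dict(_EEG_POSITIONS))
    occipital_subset: tuple = ("Oz", "O1", "O2")

    def __post_init__(self):
        if len(self.eeg_channels) != 30:
            raise ValueError("montage must have exactly 30 EEG channels")
        if not set(self.occipital_subset) <= set(self.eeg_channels):
            raise ValueError("occipital subset must be EEG channels")
        missing = set(self.eeg_channels) - set(self.positions)
        if missing:
            raise ValueError(f"positions missing for {sorted(missing)}")

    @property
    def channel_names(self) -> tuple:
        """All recorded channels: 30 EEG followed by the EOG derivations."""
        return self.eeg_channels + self.eog_channels

    def export_csv(self, path) -> None:
        """Write channel, x, y for the 30 EEG channels."""
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["channel", "x", "y"])
            for ch in self.eeg_channels:
                x, y = self.positions[ch]
                w.writerow([ch, f"{x:.4f}", f"{y:.4f}"])


def default_montage() -> Montage:
    return Montage()


# ---------------------------------------------------------------------------
# plain-text (YAML) serialization of grid and condition definitions

def grid_to_yaml(grid: LineGrid, path=None) -> str:
    doc = {
        "row_freqs": {k: float(v) for k, v in grid.row_freqs.items()},
        "col_freqs": {k: float(v) for k, v in grid.col_freqs.items()},
        "line_width_mm": float(grid.line_width_mm),
        "spacing_cm": float(grid.spacing_cm),
        "size_cm": float(grid.size_cm),
    }
    text = yaml.safe_dump(doc, sort_keys=True)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def grid_from_yaml(source) -> LineGrid:
    if hasattr(source, "read") or "\n" in str(source) or ":" in str(source):
        doc = yaml.safe_load(source if isinstance(source, str) else source.read())
    else:
        with open(source) as fh:
            doc = yaml.safe_load(fh)
    return LineGrid(**doc)


def condition_to_yaml(cond: Condition, path=None) -> str:
    doc = {
        "name": cond.name,
        "irrelevant_scale": float(cond.irrelevant_scale),
        "bottom_up_freqs": [float(f) for f in cond.bottom_up_freqs],
    }
    text = yaml.safe_dump(doc, sort_keys=True)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def condition_from_yaml(text: str) -> Condition:
    doc = yaml.safe_load(text)
    doc["bottom_up_freqs"] = tuple(doc.get("bottom_up_freqs", DEFAULT_BOTTOM_UP_FREQS))
    return Condition(**doc)
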