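"""Epoch container persistence: NPZ array archive + JSON sidecar."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .epochs import EpochSet
from .paradigm import Montage

__all__ = ["write_epochs", "read_epochs"]

SCHEMA_VERSION = 1


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_epochs(epochs: EpochSet, path) -> Path:
    """Write ``<path>.npz`` (data) plus ``<path>.json`` (metadata)."""
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    np.savez_compressed(path, data=epochs.data)
    meta = {
        "schema_version": SCHEMA_VERSION,
        "fs": float(epochs.fs),
        "labels": epochs.labels.tolist(),
        "condition": epochs.condition,
        "chrono_index": epochs.chrono_index.tolist(),
        "montage": {
            "eeg_channels": list(epochs.montage.eeg_channels),
            "eog_channels": list(epochs.montage.eog_channels),
            "positions": {k: list(map(float, v)) for k, v in epochs.montage.positions.items()},
            "occipital_subset": list(epochs.montage.occipital_subset),
        },
        "info": _jsonable(epochs.info),
        "shape": list(epochs.data.shape),
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_epochs(path, expect_fs: float | None = None) -> EpochSet:
    """Read an epoch container; validates shape and metadata.

    ``expect_fs`` cross-checks the sidecar sampling rate (no silent
    resampling): a mismatch raises.
    """
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    sidecar = _sidecar_path(path)
    if not path.exists() or not sidecar.exists():
        raise FileNotFoundError(f"missing container file(s): {path}, {sidecar}")
    meta = json.loads(sidecar.read_text())
    for key in ("fs", "labels", "condition", "chrono_index", "montage", "shape"):
        if key not in meta:
            raise ValueError(f"sidecar {sidecar} is missing required field {key!r}")
    with np.load(path) as archive:
        data = archive["data"]
    if list(data.shape) != list(meta["shape"]):
        raise ValueError(
            f"array shape {list(data.shape)} does not match sidecar {meta['shape']}"
        )
    if expect_fs is not None and not np.isclose(expect_fs, meta["fs"]):
        raise ValueError(
            f"sampling rate mismatch: sidecar has {meta['fs']} Hz, expected {expect_fs} Hz"
        )
    mdoc = meta["montage"]
    montage = Montage(
        eeg_channels=tuple(mdoc["eeg_channels"]),
        eog_channels=tuple(mdoc["eog_channels"]),
        positions={k: tuple(v) for k, v in mdoc["positions"].items()},
        occipital_subset=tuple(mdoc["occipital_subset"]),
    )
    return EpochSet(
        data=data,
        fs=meta["fs"],
        labels=np.asarray(meta["labels"]),
        condition=meta["condition"],
        montage=montage,
        chrono_index=np.asarray(meta["chrono_index"]),
        info=meta.get("info", {}),
    )
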