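"""In-memory containers and on-disk format for recording sessions.

A :class:`Session` is a continuous multichannel record (channels x
samples) with per-trial deviation-onset sample indices and reaction
times; an :class:`Epochs` object holds the extracted baseline windows
(channels x trials x samples).  Both serialize as a ``.npy`` array
plus a JSON sidecar carrying the sampling rate, channel labels, trial
metadata, seed and — for synthetic sessions — the ground-truth
specification.  Round-trips are lossless.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Session",
    "Epochs",
    "write_session",
    "read_session",
    "write_epochs",
    "read_epochs",
    "write_behavior",
    "read_behavior",
]

SCHEMA_VERSION = 1


@dataclass
class Session:
    """Continuous multichannel recording with trial events.

    ``data`` has shape (n_channels, n_samples); ``onsets`` are
    deviation-onset sample indices (one per trial, increasing);
    ``rts`` are per-trial reaction times in seconds.
    """

    data: np.ndarray
    fs: float
    channels: list[str]
    onsets: np.ndarray
    rts: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.onsets = np.asarray(self.onsets, dtype=int)
        self.rts = np.asarray(self.rts, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("session data must be channels x samples")
        if len(self.channels) != self.data.shape[0]:
            raise ValueError("channel label count does not match data rows")
        if self.onsets.shape != self.rts.shape:
            raise ValueError(
                f"{self.onsets.size} onsets but {self.rts.size} RTs: every "
                "trial needs both"
            )

    @property
    def n_trials(self) -> int:
        return self.onsets.size


@dataclass
class Epochs:
    """Baseline epochs: channels x trials x samples plus bookkeeping.

    ``trial_index`` maps each epoch back to its source-session trial
    (epochs may be fewer than session trials when some were dropped).
    """

    data: np.ndarray
    fs: float
    channels: list[str]
    trial_index: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.trial_index = np.asarray(self.trial_index, dtype=int)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be channels x trials x samples")
        if len(self.channels) != self.data.shape[0]:
            raise ValueError("channel label count does not match data rows")
        if self.trial_index.size != self.data.shape[1]:
            raise ValueError("trial_index length does not match trial axis")

    @property
    def n_trials(self) -> int:
        return self.data.shape[1]

    def channel(self, label: str) -> np.ndarray:
        """Trials x samples array for one channel label."""
        try:
            i = self.channels.index(label)
        except ValueError:
            raise KeyError(f"unknown channel {label!r}") from None
        return self.data[i]


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_session(session: Session, path) -> Path:
    """Write ``<path>.npy`` + ``<path>.json``; returns the array path."""
    path = Path(path).with_suffix(".npy")
    np.save(path, session.data)
    sidecar = {
        "schema_version": SCHEMA_VERSION,
        "kind": "session",
        "fs": session.fs,
        "channels": session.channels,
        "shape": list(session.data.shape),
        "onsets": session.onsets.tolist(),
        "rts": session.rts.tolist(),
        "meta": _jsonable(session.meta),
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def _load_sidecar(path: Path, kind: str) -> dict:
    sidecar = json.loads(_sidecar_path(path).read_text())
    if sidecar.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(
            f"unsupported schema version {sidecar.get('schema_version')!r}"
        )
    if sidecar.get("kind") != kind:
        raise ValueError(f"sidecar kind {sidecar.get('kind')!r}, expected {kind!r}")
    return sidecar


def read_session(path) -> Session:
    path = Path(path).with_suffix(".npy")
    sidecar = _load_sidecar(path, "session")
    data = np.load(path)
    if list(data.shape) != sidecar["shape"]:
        raise ValueError(
            f"array shape {list(data.shape)} disagrees with sidecar "
            f"{sidecar['shape']}"
        )
    n_trials = len(sidecar["onsets"])
    if len(sidecar["rts"]) != n_trials:
        missing = [i for i in range(n_trials) if i >= len(sidecar["rts"])]
        raise ValueError(f"missing RT for trial(s) {missing}")
    return Session(
        data=data,
        fs=sidecar["fs"],
        channels=list(sidecar["channels"]),
        onsets=np.asarray(sidecar["onsets"], dtype=int),
        rts=np.asarray(sidecar["rts"], dtype=float),
        meta=sidecar.get("meta", {}),
    )


def write_epochs(epochs: Epochs, path) -> Path:
    path = Path(path).with_suffix(".npy")
    np.save(path, epochs.data)
    sidecar = {
        "schema_version": SCHEMA_VERSION,
        "kind": "epochs",
        "fs": epochs.fs,
        "channels": epochs.channels,
        "shape": list(epochs.data.shape),
        "trial_index": epochs.trial_index.tolist(),
        "meta": _jsonable(epochs.meta),
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def read_epochs(path) -> Epochs:
    path = Path(path).with_suffix(".npy")
    sidecar = _load_sidecar(path, "epochs")
    data = np.load(path)
    if list(data.shape) != sidecar["shape"]:
        raise ValueError(
            f"array shape {list(data.shape)} disagrees with sidecar "
            f"{sidecar['shape']}"
        )
    return Epochs(
        data=data,
        fs=sidecar["fs"],
        channels=list(sidecar["channels"]),
        trial_index=np.asarray(sidecar["trial_index"], dtype=int),
        meta=sidecar.get("meta", {}),
    )


def write_behavior(table: pd.DataFrame, path) -> Path:
    """CSV export of the per-trial behavior table."""
    path = Path(path)
    table.to_csv(path, index=False)
    return path


def read_behavior(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    required = {"trial_index", "rt_s", "normalized_rt", "dp", "group"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"behavior table missing columns {sorted(missing)}")
    return table
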