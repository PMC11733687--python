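"""Epoched EEG container and its HDF5 serialization.

The :class:`Epochs` object is the currency of the whole pipeline: a
``trials x channels x samples`` amplitude array (µV) plus a millisecond
time axis, channel labels, a per-trial metadata table and the identity of
the recording (subject, group, session, stimulated ear).

On disk an epochs file is plain HDF5 with members ``/data``, ``/time``,
``/channels`` and a ``/trials`` group holding one dataset per metadata
column; subject/group/session/ear/fs live in the root attributes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

GROUPS = ("implanted", "control")
SESSIONS = ("pre-op", "3m", "6m", "12m", "reference")
EARS = ("CI", "non-CI", "earphone")


@dataclass
class Epochs:
    """Single-recording epoched data.

    Parameters
    ----------
    data : ndarray, shape (n_trials, n_channels, n_samples)
        Amplitudes in µV.
    fs : float
        Sampling rate in Hz.
    times : ndarray, shape (n_samples,)
        Time axis in ms relative to stimulus onset.
    ch_names : sequence of str
    trials : DataFrame
        One row per trial; typically ``condition``, ``word_id``, ``rating``.
    """

    data: np.ndarray
    fs: float
    times: np.ndarray
    ch_names: Sequence[str]
    trials: pd.DataFrame
    subject: str = ""
    group: str = ""
    session: str = ""
    ear: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.times = np.asarray(self.times, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, channels, samples)")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.times.shape[0] != self.data.shape[2]:
            raise ValueError(
                f"time axis length {self.times.shape[0]} does not match "
                f"samples {self.data.shape[2]}"
            )
        if len(self.ch_names) != self.data.shape[1]:
            raise ValueError("channel label count does not match data")
        if len(self.trials) != self.data.shape[0]:
            raise ValueError("trials table length does not match data")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def copy(self) -> "Epochs":
        return replace(
            self,
            data=self.data.copy(),
            times=self.times.copy(),
            ch_names=list(self.ch_names),
            trials=self.trials.copy(),
        )

    def time_index(self, t_ms: float) -> int:
        """Index of the sample nearest to ``t_ms`` (must lie on the axis)."""
        i = int(np.argmin(np.abs(self.times - t_ms)))
        if abs(self.times[i] - t_ms) > 1000.0 / self.fs:
            raise ValueError(f"time {t_ms} ms outside epoch axis")
        return i

    def condition_mask(self, condition: str) -> np.ndarray:
        if "condition" not in self.trials.columns:
            raise ValueError("trials table has no 'condition' column")
        return (self.trials["condition"] == condition).to_numpy()

    def select_trials(self, mask: np.ndarray) -> "Epochs":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask.astype(int)
        return replace(
            self,
            data=self.data[idx],
            trials=self.trials.iloc[idx].reset_index(drop=True),
        )

    def content_hash(self) -> str:
        """Deterministic SHA-256 over data and metadata."""
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.data).tobytes())
        h.update(np.ascontiguousarray(self.times).tobytes())
        h.update(json.dumps(list(self.ch_names)).encode())
        h.update(self.trials.to_csv(index=False).encode())
        h.update(
            f"{self.subject}|{self.group}|{self.session}|{self.ear}|{self.fs}".encode()
        )
        return h.hexdigest()


def save_epochs(e: Epochs, path: str | Path) -> Path:
    """Write an :class:`Epochs` to HDF5. Returns the path written."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=e.data)
        f.create_dataset("time", data=e.times)
        f.create_dataset(
            "channels", data=np.array([str(c) for c in e.ch_names], dtype="S")
        )
        g = f.create_group("trials")
        for col in e.trials.columns:
            vals = e.trials[col].to_numpy()
            if vals.dtype == object or vals.dtype.kind in "US":
                vals = np.array([str(v) for v in vals], dtype="S")
            g.create_dataset(col, data=vals)
        g.attrs["columns"] = json.dumps(list(e.trials.columns))
        for k in ("subject", "group", "session", "ear"):
            f.attrs[k] = getattr(e, k)
        f.attrs["fs"] = e.fs
    return path


def load_epochs(path: str | Path) -> Epochs:
    """Read an epochs HDF5 file; errors name the first missing member."""
    path = Path(path)
    with h5py.File(path, "r") as f:
        for member in ("data", "time", "channels", "trials"):
            if member not in f:
                raise KeyError(f"epochs container {path} is missing /{member}")
        data = f["data"][()]
        times = f["time"][()]
        ch_names = [c.decode() for c in f["channels"][()]]
        g = f["trials"]
        cols = json.loads(g.attrs["columns"])
        table = {}
        for col in cols:
            vals = g[col][()]
            if vals.dtype.kind == "S":
                vals = np.array([v.decode() for v in vals])
            table[col] = vals
        trials = pd.DataFrame(table, columns=cols)
        kwargs = {k: f.attrs[k] for k in ("subject", "group", "session", "ear")}
        fs = float(f.attrs["fs"])
    return Epochs(
        data=data, fs=fs, times=times, ch_names=ch_names, trials=trials, **kwargs
    )


@dataclass
class ManifestEntry:
    subject: str
    group: str
    session: str
    ear: str
    path: str
    seed: int
    stage: str
    content_hash: str


@dataclass
class StudyManifest:
    """Provenance record of every dataset a pipeline run produced."""

    entries: list[ManifestEntry] = field(default_factory=list)
    config: dict = field(default_factory=dict)

    def add(self, entry: ManifestEntry) -> None:
        self.entries.append(entry)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "config": self.config,
            "entries": [vars(en) for en in self.entries],
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "StudyManifest":
        payload = json.loads(Path(path).read_text())
        m = cls(config=payload["config"])
        for en in payload["entries"]:
            m.add(ManifestEntry(**en))
        return m
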