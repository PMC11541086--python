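"""Multichannel time-series container and plain-text I/O.

A :class:`Recording` is the carrier for every signal in the package:
single-region series, paired-region recordings, and multichannel EEG.
Data are stored channels x samples.  Recordings round-trip through a
delimited text matrix (one row per channel) plus a JSON sidecar holding
the sampling rate, channel labels, and units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["Recording", "EpochSet", "read_recording", "write_recording"]


@dataclass
class Recording:
    """A multichannel time series with sampling rate and channel labels.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal values in microvolts (or arbitrary units).
    fs : float
        Sampling rate in Hz. Must be positive.
    channel_labels : list of str, optional
        One label per channel; defaults to ``ch00, ch01, ...``.
    units : str
        Unit string recorded in the sidecar, purely descriptive.
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str] = field(default_factory=list)
    units: str = "uV"

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.ndim != 2:
            raise ValueError("data must be a channels x samples matrix")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.data.shape[0] < 1 or self.data.shape[1] < 2:
            raise ValueError(
                "recording needs at least 1 channel and 2 samples, got "
                f"shape {self.data.shape}"
            )
        if not self.channel_labels:
            self.channel_labels = [f"ch{i:02d}" for i in range(self.n_channels)]
        if len(self.channel_labels) != self.n_channels:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.n_channels} channels"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def channel(self, label: str) -> np.ndarray:
        """Return one channel as a 1-D array, by label."""
        try:
            idx = self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"no channel labeled {label!r}") from None
        return self.data[idx]

    def pick(self, labels: list[str]) -> "Recording":
        """Sub-recording restricted to ``labels`` (order preserved)."""
        missing = [lb for lb in labels if lb not in self.channel_labels]
        if missing:
            raise KeyError(f"channels not in recording: {missing}")
        idx = [self.channel_labels.index(lb) for lb in labels]
        return Recording(self.data[idx].copy(), self.fs, list(labels), self.units)


@dataclass
class EpochSet:
    """Stimulus-locked epochs: ``data`` is (n_epochs, n_channels, n_samples).

    ``times`` gives seconds relative to the stimulus (t=0 included for
    any epoch spanning it).
    """

    data: np.ndarray
    times: np.ndarray
    fs: float
    channel_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be (n_epochs, n_channels, n_samples)")
        if self.times.shape != (self.data.shape[2],):
            raise ValueError("times length must match the sample axis")
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i:02d}" for i in range(self.data.shape[1])]
        if len(self.channel_labels) != self.data.shape[1]:
            raise ValueError("channel label count mismatch")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def average(self) -> np.ndarray:
        """Evoked response: mean across epochs, (n_channels, n_samples)."""
        return self.data.mean(axis=0)


def write_recording(rec: Recording, path: str | Path, delimiter: str = "\t") -> None:
    """Write a recording as a delimited matrix plus ``<path>.json`` sidecar."""
    path = Path(path)
    np.savetxt(path, rec.data, delimiter=delimiter)
    sidecar = {
        "fs": rec.fs,
        "channel_labels": rec.channel_labels,
        "units": rec.units,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_recording(path: str | Path, delimiter: str = "\t") -> Recording:
    """Read a recording written by :func:`write_recording`."""
    path = Path(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    data = np.loadtxt(path, delimiter=delimiter, ndmin=2)
    return Recording(
        data,
        fs=float(meta["fs"]),
        channel_labels=list(meta.get("channel_labels", [])),
        units=meta.get("units", "uV"),
    )
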