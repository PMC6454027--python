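"""Shared in-memory containers and their HDF5 on-disk forms.

Conventions used throughout the package:

* time is expressed in milliseconds relative to stimulus onset; sample ``k``
  of an epoch corresponds to ``t_start_ms + k * step_ms``;
* epoch arrays are indexed ``(subject, condition, trial, channel, time)``;
* RDMs are square ``condition x condition`` matrices, symmetric, with the
  (undefined) diagonal stored as NaN.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import h5py
import numpy as np

__all__ = ["EpochSet", "RDMSeries", "time_axis", "n_time_samples"]


def n_time_samples(t_start_ms: float, t_stop_ms: float, step_ms: float) -> int:
    """Number of samples in the inclusive window [t_start_ms, t_stop_ms]."""
    if step_ms <= 0:
        raise ValueError("step_ms must be positive")
    return int(np.floor((t_stop_ms - t_start_ms) / step_ms)) + 1


def time_axis(t_start_ms: float, t_stop_ms: float, step_ms: float) -> np.ndarray:
    """Sample times (ms) for the inclusive window, endpoints included."""
    n = n_time_samples(t_start_ms, t_stop_ms, step_ms)
    return t_start_ms + step_ms * np.arange(n, dtype=float)


@dataclass
class EpochSet:
    """Epoched multichannel recordings for a group of subjects.

    Parameters
    ----------
    data
        Array of shape ``(n_subjects, n_conditions, n_trials, n_channels,
        n_time)``; units are arbitrary for synthetic data (femtotesla for
        real MEG).
    t_start_ms, step_ms
        Epoch window origin and sampling step.
    channel_labels
        One label per channel; ``frontal_channels`` must be a subset.
    valid
        Boolean per-trial validity flags, shape ``(n_subjects,
        n_conditions, n_trials)``; trials flagged False are excluded from
        decoding.
    """

    data: np.ndarray
    t_start_ms: float
    step_ms: float
    channel_labels: list[str] = field(default_factory=list)
    frontal_channels: list[str] = field(default_factory=list)
    condition_labels: list[str] = field(default_factory=list)
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 5:
            raise ValueError(
                "epoch data must be 5-dimensional "
                "(subject, condition, trial, channel, time); got shape "
                f"{self.data.shape}"
            )
        ns, nc, nt, nch, _ = self.data.shape
        if not self.channel_labels:
            self.channel_labels = [f"CH{i:03d}" for i in range(nch)]
        if len(self.channel_labels) != nch:
            raise ValueError("channel_labels length does not match data")
        missing = set(self.frontal_channels) - set(self.channel_labels)
        if missing:
            raise ValueError(f"frontal channels not in channel_labels: {sorted(missing)}")
        if not self.condition_labels:
            self.condition_labels = [f"cond_{i:03d}" for i in range(nc)]
        if self.valid is None:
            self.valid = np.ones((ns, nc, nt), dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.shape != (ns, nc, nt):
            raise ValueError("valid flags shape does not match data")

    # -- shape accessors -------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.data.shape[1]

    @property
    def n_trials(self) -> int:
        return self.data.shape[2]

    @property
    def n_channels(self) -> int:
        return self.data.shape[3]

    @property
    def n_time(self) -> int:
        return self.data.shape[4]

    @property
    def times(self) -> np.ndarray:
        return self.t_start_ms + self.step_ms * np.arange(self.n_time, dtype=float)

    @property
    def frontal_indices(self) -> np.ndarray:
        idx = {c: i for i, c in enumerate(self.channel_labels)}
        return np.array([idx[c] for c in self.frontal_channels], dtype=int)

    def with_data(self, data: np.ndarray, valid: np.ndarray | None = None) -> "EpochSet":
        """Copy carrying new samples (and optionally new validity flags).

        If the new data changes the (subject, condition, trial) shape and
        no flags are supplied, validity resets to all-valid.
        """
        data = np.asarray(data, dtype=float)
        if valid is None:
            valid = self.valid if self.valid.shape == data.shape[:3] else None
        return replace(self, data=data, valid=valid)

    # -- persistence -----------------------------------------------------
    def to_hdf5(self, path) -> None:
        """Write one group per subject with an ``epochs`` dataset.

        Window metadata is stored as group attributes ``t_start_ms``,
        ``step_ms`` and ``condition_labels``.
        """
        with h5py.File(path, "w") as f:
            f.attrs["n_subjects"] = self.n_subjects
            f.attrs["channel_labels"] = json.dumps(self.channel_labels)
            f.attrs["frontal_channels"] = json.dumps(self.frontal_channels)
            for s in range(self.n_subjects):
                g = f.create_group(f"subject_{s:03d}")
                g.create_dataset("epochs", data=self.data[s])
                g.create_dataset("valid", data=self.valid[s])
                g.attrs["t_start_ms"] = self.t_start_ms
                g.attrs["step_ms"] = self.step_ms
                g.attrs["condition_labels"] = json.dumps(self.condition_labels)

    @classmethod
    def from_hdf5(cls, path) -> "EpochSet":
        with h5py.File(path, "r") as f:
            names = sorted(k for k in f.keys() if k.startswith("subject_"))
            if not names:
                raise ValueError(f"no subject groups found in {path}")
            data = np.stack([f[n]["epochs"][()] for n in names])
            valid = np.stack([f[n]["valid"][()] for n in names]).astype(bool)
            g0 = f[names[0]]
            return cls(
                data=data,
                t_start_ms=float(g0.attrs["t_start_ms"]),
                step_ms=float(g0.attrs["step_ms"]),
                channel_labels=json.loads(f.attrs["channel_labels"]),
                frontal_channels=json.loads(f.attrs["frontal_channels"]),
                condition_labels=json.loads(g0.attrs["condition_labels"]),
                valid=valid,
            )


@dataclass
class RDMSeries:
    """Per-subject series of condition x condition RDMs over time.

    ``data`` has shape ``(n_subjects, n_time, n_conditions, n_conditions)``
    with NaN on the diagonal (dissimilarity of a condition with itself is
    undefined). For decoding RDMs the cells are pairwise classification
    accuracies in [0, 1].
    """

    data: np.ndarray
    times: np.ndarray
    condition_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 4 or self.data.shape[2] != self.data.shape[3]:
            raise ValueError(f"RDM series must be (subject, time, cond, cond); got {self.data.shape}")
        if self.data.shape[1] != self.times.size:
            raise ValueError("time axis length does not match data")
        if not self.condition_labels:
            self.condition_labels = [f"cond_{i:03d}" for i in range(self.data.shape[2])]

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.data.shape[2]

    def grand_average(self) -> np.ndarray:
        """Mean RDM series over subjects, shape (time, cond, cond).

        Cells missing in every subject (the diagonal, excluded
        conditions) stay NaN.
        """
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.data, axis=0)

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("rdms", data=self.data)
            f.create_dataset("time_ms", data=self.times)
            f.attrs["condition_labels"] = json.dumps(self.condition_labels)
            f.attrs["missing_value"] = "NaN"

    @classmethod
    def from_hdf5(cls, path) -> "RDMSeries":
        with h5py.File(path, "r") as f:
            return cls(
                data=f["rdms"][()],
                times=f["time_ms"][()],
                condition_labels=json.loads(f.attrs["condition_labels"]),
            )
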