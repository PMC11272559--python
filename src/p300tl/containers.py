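"""In-memory containers for continuous EEG, epoched trials and feature sets.

The containers are deliberately small dataclasses around numpy arrays plus a
pandas events/metadata table, with HDF5 round-tripping.  Time is always the
first signal axis; channels the second.  Epochs are stacked as (n, T, C).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

EVENT_COLUMNS = ["sample_index", "code", "is_target", "character_index", "repetition_index"]


def _as_events_frame(events) -> pd.DataFrame:
    df = pd.DataFrame(events, columns=EVENT_COLUMNS) if not isinstance(events, pd.DataFrame) else events.copy()
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"events table missing columns {missing}")
    return df.reset_index(drop=True).astype(
        {"sample_index": np.int64, "code": np.int64, "is_target": np.int64,
         "character_index": np.int64, "repetition_index": np.int64}
    )


@dataclass
class ContinuousRecording:
    """Multichannel signal (time x channels, microvolts) with stimulus events.

    ``events`` has one row per stimulus with columns ``sample_index``
    (onset, samples), ``code`` (1-6 row / 7-12 column flashes for the
    speller; 0/1 for RSVP), ``is_target``, ``character_index`` and
    ``repetition_index`` (-1 where not applicable).
    """

    signal: np.ndarray
    fs: float
    events: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=EVENT_COLUMNS))

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim != 2:
            raise ValueError("signal must be 2-D (time x channels)")
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        self.events = _as_events_frame(self.events)
        if len(self.events) and (
            (self.events.sample_index < 0).any()
            or (self.events.sample_index >= len(self.signal)).any()
        ):
            raise ValueError("event sample_index outside the recording")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[1]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[0]

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("signal", data=self.signal)
            f.attrs["fs"] = float(self.fs)
            g = f.create_group("events")
            for col in EVENT_COLUMNS:
                g.create_dataset(col, data=self.events[col].to_numpy())

    @classmethod
    def load(cls, path) -> "ContinuousRecording":
        with h5py.File(path, "r") as f:
            signal = f["signal"][()]
            fs = float(f.attrs["fs"])
            events = pd.DataFrame({col: f["events"][col][()] for col in EVENT_COLUMNS})
        return cls(signal=signal, fs=fs, events=events)


@dataclass
class EpochSet:
    """Stack of stimulus-locked epochs (n, T, C) with per-epoch metadata.

    ``meta`` carries one row per epoch: label (0/1), code, character_index,
    repetition_index.
    """

    epochs: np.ndarray
    fs: float
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=np.float64)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be 3-D (n, T, C)")
        self.meta = self.meta.reset_index(drop=True)
        if len(self.meta) != len(self.epochs):
            raise ValueError("metadata length does not match epoch count")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValueError("labels must be binary")

    @property
    def labels(self) -> np.ndarray:
        return self.meta["label"].to_numpy(dtype=np.int64)

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def shape_tc(self) -> tuple[int, int]:
        return self.epochs.shape[1], self.epochs.shape[2]

    def subset(self, idx) -> "EpochSet":
        idx = np.asarray(idx)
        return EpochSet(self.epochs[idx], self.fs, self.meta.iloc[idx])

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("epochs", data=self.epochs)
            f.attrs["fs"] = float(self.fs)
            g = f.create_group("meta")
            for col in self.meta.columns:
                g.create_dataset(col, data=self.meta[col].to_numpy())

    @classmethod
    def load(cls, path) -> "EpochSet":
        with h5py.File(path, "r") as f:
            epochs = f["epochs"][()]
            fs = float(f.attrs["fs"])
            meta = pd.DataFrame({col: f["meta"][col][()] for col in f["meta"]})
        return cls(epochs=epochs, fs=fs, meta=meta)


@dataclass
class FeatureSet:
    """Per-epoch feature vectors (n, f) with the epoch metadata carried over."""

    features: np.ndarray
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float64)
        if self.features.ndim != 2:
            raise ValueError("features must be 2-D (n, f)")
        self.meta = self.meta.reset_index(drop=True)
        if len(self.meta) != len(self.features):
            raise ValueError("metadata length does not match feature count")

    @property
    def labels(self) -> np.ndarray:
        return self.meta["label"].to_numpy(dtype=np.int64)

    @property
    def dim(self) -> int:
        return self.features.shape[1]

    def __len__(self) -> int:
        return len(self.features)

    def subset(self, idx) -> "FeatureSet":
        idx = np.asarray(idx)
        return FeatureSet(self.features[idx], self.meta.iloc[idx])

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("features", data=self.features)
            g = f.create_group("meta")
            for col in self.meta.columns:
                g.create_dataset(col, data=self.meta[col].to_numpy())

    @classmethod
    def load(cls, path) -> "FeatureSet":
        with h5py.File(path, "r") as f:
            features = f["features"][()]
            meta = pd.DataFrame({col: f["meta"][col][()] for col in f["meta"]})
        return cls(features=features, meta=meta)


def concat_features(a: FeatureSet, b: FeatureSet) -> FeatureSet:
    if a.dim != b.dim:
        raise ValueError("feature dimensions differ")
    cols = [c for c in a.meta.columns if c in b.meta.columns]
    return FeatureSet(
        np.vstack([a.features, b.features]),
        pd.concat([a.meta[cols], b.meta[cols]], ignore_index=True),
    )
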