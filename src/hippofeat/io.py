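"""Recording data model and file I/O.

A :class:`RecordingSegment` is one condition's multi-channel signal block
(channels x samples, microvolts) plus ordered per-channel metadata. Segments
round-trip through a simple fixture container (``.npz`` signals + sidecar
CSV metadata) and can additionally be read from European Data Format (EDF)
files via :mod:`mne` (read-only).
"""
from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

#: minimal sampling rate: analysis ceiling is 800 Hz, so Nyquist must exceed it
MIN_FS_HZ = 1600.0

METADATA_COLUMNS = [
    "channel_id",
    "subject_id",
    "electrode_id",
    "contact_index",
    "hippocampus_id",
    "label",
]

VALID_LABELS = {"EH", "NEH", "unknown"}


class FormatError(ValueError):
    """File cannot be parsed in the expected format."""


class SchemaError(ValueError):
    """A table is missing required columns."""


class ConsistencyError(ValueError):
    """Metadata and signals disagree, or metadata is internally inconsistent."""


@dataclass(frozen=True)
class ChannelInfo:
    """Identity and anatomical grouping of one iEEG contact."""

    channel_id: str
    subject_id: str
    electrode_id: str
    contact_index: int
    hippocampus_id: str
    label: str = "unknown"

    def __post_init__(self):
        if self.label not in VALID_LABELS:
            raise ConsistencyError(
                f"channel {self.channel_id}: label {self.label!r} not in {sorted(VALID_LABELS)}"
            )


@dataclass
class RecordingSegment:
    """One condition's multi-channel iEEG block.

    Attributes
    ----------
    signals : (n_channels, n_samples) float array, microvolts
    fs : sampling rate, Hz
    channels : ordered channel metadata, one entry per signal row
    condition : "rest" or "task"
    task_name : task identifier or None (rest)
    """

    signals: np.ndarray
    fs: float
    channels: list[ChannelInfo]
    condition: str = "rest"
    task_name: str | None = None

    def __post_init__(self):
        self.signals = np.atleast_2d(np.asarray(self.signals, dtype=float))
        if self.signals.shape[0] == 0 or self.signals.shape[1] == 0:
            raise ConsistencyError("segment has no channels or no samples")
        if len(self.channels) != self.signals.shape[0]:
            raise ConsistencyError(
                f"{len(self.channels)} metadata rows for {self.signals.shape[0]} signal channels"
            )
        if self.fs < MIN_FS_HZ:
            raise ConsistencyError(
                f"fs={self.fs} Hz too low: need > {MIN_FS_HZ} Hz for the 800 Hz analysis ceiling"
            )
        if self.condition not in ("rest", "task"):
            raise ConsistencyError(f"condition must be 'rest' or 'task', got {self.condition!r}")
        ids = [c.channel_id for c in self.channels]
        if len(set(ids)) != len(ids):
            raise ConsistencyError("duplicate channel_id in segment metadata")

    @property
    def n_channels(self) -> int:
        return self.signals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, channel_id: str) -> np.ndarray:
        for i, c in enumerate(self.channels):
            if c.channel_id == channel_id:
                return self.signals[i]
        raise KeyError(channel_id)


# ---------------------------------------------------------------------------
# channel metadata table


def read_channel_metadata(path: str | Path) -> list[ChannelInfo]:
    """Read a channel metadata CSV (header: channel_id,subject_id,...)."""
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"metadata table missing columns: {missing}")
    if df["channel_id"].duplicated().any():
        dups = df.loc[df["channel_id"].duplicated(), "channel_id"].tolist()
        raise ConsistencyError(f"duplicate channel_id values: {dups}")
    infos = [
        ChannelInfo(
            channel_id=row.channel_id,
            subject_id=row.subject_id,
            electrode_id=row.electrode_id,
            contact_index=int(row.contact_index),
            hippocampus_id=row.hippocampus_id,
            label=row.label,
        )
        for row in df.itertuples()
    ]
    seen = set()
    for c in infos:
        key = (c.subject_id, c.electrode_id, c.contact_index)
        if key in seen:
            raise ConsistencyError(f"duplicate (electrode, contact) within subject: {key}")
        seen.add(key)
    return infos


def write_channel_metadata(channels: Sequence[ChannelInfo], path: str | Path) -> None:
    pd.DataFrame([asdict(c) for c in channels])[METADATA_COLUMNS].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# fixture container (.npz + CSV sidecar)


def write_recording(segment: RecordingSegment, path: str | Path) -> None:
    """Write a segment to the package's fixture container.

    ``<path>`` gets the signals (float64 ``.npz``) and ``<path stem>.channels.csv``
    the metadata sidecar.
    """
    path = Path(path)
    np.savez(
        path,
        signals=segment.signals,
        fs=segment.fs,
        condition=segment.condition,
        task_name="" if segment.task_name is None else segment.task_name,
    )
    write_channel_metadata(segment.channels, _sidecar(path))


def _sidecar(path: Path) -> Path:
    stem = path.name[:-4] if path.name.endswith(".npz") else path.name
    return path.with_name(stem + ".channels.csv")


def read_recording(path: str | Path, format_hint: str | None = None) -> RecordingSegment:
    """Read a recording segment.

    ``format_hint`` may be ``"edf"`` or ``"npz"``; by default it is inferred
    from the file extension.
    """
    path = Path(path)
    if not path.exists():
        candidate = path.with_name(path.name + ".npz")
        if candidate.exists():
            path = candidate
        else:
            raise FileNotFoundError(path)
    fmt = format_hint or path.suffix.lstrip(".").lower()
    if fmt == "edf":
        return _read_edf(path)
    if fmt == "npz":
        return _read_npz(path)
    raise FormatError(f"unknown recording format {fmt!r} for {path}")


def _read_npz(path: Path) -> RecordingSegment:
    try:
        with np.load(path, allow_pickle=False) as z:
            signals = z["signals"]
            fs = float(z["fs"])
            condition = str(z["condition"])
            task_name = str(z["task_name"]) or None
    except (KeyError, OSError, ValueError) as exc:
        raise FormatError(f"cannot read fixture container {path}: {exc}") from exc
    channels = read_channel_metadata(_sidecar(path))
    return RecordingSegment(signals, fs, channels, condition=condition, task_name=task_name)


def _read_edf(path: Path) -> RecordingSegment:
    import mne

    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # mne raises various concrete types
        raise FormatError(f"cannot read EDF {path}: {exc}") from exc
    if len(raw.ch_names) == 0:
        raise ConsistencyError(f"EDF {path} contains no channels")
    signals = raw.get_data() * 1e6  # mne returns volts; the pipeline uses microvolts
    sidecar = _sidecar(path)
    if sidecar.exists():
        channels = read_channel_metadata(sidecar)
        names = {c.channel_id for c in channels}
        if names != set(raw.ch_names):
            raise ConsistencyError(
                f"EDF channels {sorted(raw.ch_names)} do not match sidecar {sorted(names)}"
            )
        order = {c.channel_id: c for c in channels}
        channels = [order[name] for name in raw.ch_names]
    else:
        channels = [
            ChannelInfo(name, "unknown", "unknown", i, "unknown", "unknown")
            for i, name in enumerate(raw.ch_names)
        ]
    return RecordingSegment(signals, float(raw.info["sfreq"]), channels)


# ---------------------------------------------------------------------------
# event tables

HFO_EVENT_COLUMNS = [
    "channel_id",
    "t_start",
    "t_end",
    "duration_ms",
    "f_min",
    "f_max",
    "peak_frequency",
    "relative_amplitude",
    "band_label",
]

IED_EVENT_COLUMNS = ["channel_id", "t_peak", "amplitude_uv", "slope"]


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    events.to_csv(path, index=False)


def read_events(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
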