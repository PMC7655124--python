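"""Per-channel iEEG feature aggregation.

The 14 per-channel features, per condition:

========  =====================================================
r_rate    ripple rate, events / 10 min
fr_rate   fast-ripple rate, events / 10 min
r_amp     mean ripple relative amplitude (envelope z, unitless)
fr_amp    mean fast-ripple relative amplitude
r_freq    mean ripple dominant frequency, Hz
fr_freq   mean fast-ripple dominant frequency, Hz
r_dur     mean ripple duration, ms
fr_dur    mean fast-ripple duration, ms
ied_rate  spike rate, events / 10 min
ied_amp   mean spike amplitude, µV
r_corr    mean ripple-band linear correlation with adjacent contacts
fr_corr   mean fast-ripple-band linear correlation
r_ren     mean ripple-band relative entropy
fr_ren    mean fast-ripple-band relative entropy
========  =====================================================

Rates are always normalized to a 10-minute basis regardless of segment
length. Event-derived means (amplitude, frequency, duration) are missing
— not zero — when the channel has no events of that class.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .connectivity import ConnectivityExtractor, channel_connectivity_summary
from .hfo import HfoDetector
from .ied import IedDetector
from .io import RecordingSegment

FEATURE_NAMES = [
    "r_rate", "fr_rate", "r_amp", "fr_amp", "r_freq", "fr_freq",
    "r_dur", "fr_dur", "ied_rate", "ied_amp", "r_corr", "fr_corr",
    "r_ren", "fr_ren",
]

META_COLUMNS = ["channel_id", "subject_id", "hippocampus_id", "label", "condition", "task_name"]


def aggregate_features(
    hfo_events: pd.DataFrame,
    ied_events: pd.DataFrame,
    conn_summary: pd.DataFrame,
    segment_duration_s: float,
    channel_id: str,
) -> dict:
    """The 14-feature vector for one channel from its event/connectivity tables.

    Rates are ``count * 600 / duration``; per-event features are plain
    means over that channel's events; connectivity values are copied from
    the per-channel summary. Missing classes yield rate 0 and missing
    (NaN) event-feature fields.
    """
    scale = 600.0 / segment_duration_s
    out: dict = {"channel_id": channel_id}
    hfo = hfo_events[hfo_events["channel_id"] == channel_id] if len(hfo_events) else hfo_events
    for band, prefix in (("R", "r"), ("FR", "fr")):
        ev = hfo[hfo["band_label"] == band] if len(hfo) else hfo
        out[f"{prefix}_rate"] = len(ev) * scale
        out[f"{prefix}_amp"] = float(ev["relative_amplitude"].mean()) if len(ev) else np.nan
        out[f"{prefix}_freq"] = float(ev["peak_frequency"].mean()) if len(ev) else np.nan
        out[f"{prefix}_dur"] = float(ev["duration_ms"].mean()) if len(ev) else np.nan
    ied = ied_events[ied_events["channel_id"] == channel_id] if len(ied_events) else ied_events
    out["ied_rate"] = len(ied) * scale
    out["ied_amp"] = float(ied["amplitude_uv"].mean()) if len(ied) else np.nan
    for band, prefix in (("R", "r"), ("FR", "fr")):
        row = conn_summary[
            (conn_summary["channel_id"] == channel_id) & (conn_summary["band"] == band)
        ] if len(conn_summary) else conn_summary
        out[f"{prefix}_corr"] = float(row["corr"].iloc[0]) if len(row) else np.nan
        out[f"{prefix}_ren"] = float(row["ren"].iloc[0]) if len(row) else np.nan
    return out


def extract_segment_features(
    segment: RecordingSegment,
    hfo_detector: HfoDetector | None = None,
    ied_detector: IedDetector | None = None,
    connectivity: ConnectivityExtractor | None = None,
) -> pd.DataFrame:
    """Run all detectors on one segment and aggregate per-channel features."""
    hfo_detector = hfo_detector or HfoDetector()
    ied_detector = ied_detector or IedDetector()
    connectivity = connectivity or ConnectivityExtractor()
    hfo_ev = hfo_detector.detect_segment(segment)
    ied_ev = ied_detector.detect_segment(segment)
    conn = channel_connectivity_summary(connectivity.transform(segment))
    rows = []
    for c in segment.channels:
        row = aggregate_features(hfo_ev, ied_ev, conn, segment.duration_s, c.channel_id)
        row.update(
            subject_id=c.subject_id,
            hippocampus_id=c.hippocampus_id,
            label=c.label,
            condition=segment.condition,
            task_name=segment.task_name,
        )
        rows.append(row)
    return pd.DataFrame(rows)[META_COLUMNS + FEATURE_NAMES]


def extract_cohort_features(
    segments: list[RecordingSegment], config: PipelineConfig | None = None
) -> pd.DataFrame:
    """Feature table for a whole cohort (one row per channel x segment)."""
    cfg = config or PipelineConfig()
    hfo = HfoDetector.from_config(cfg.hfo)
    ied = IedDetector.from_config(cfg.ied)
    conn = ConnectivityExtractor.from_config(cfg.connectivity)
    frames = [extract_segment_features(s, hfo, ied, conn) for s in segments]
    return pd.concat(frames, ignore_index=True)


def grouped_task_reduce(features: pd.DataFrame) -> pd.DataFrame:
    """Collapse per-task rows to one task row per channel (element-wise mean).

    When a subject performed several tasks, each feature's grouped-task
    value is the mean across tasks, ignoring missing values. Rest rows
    pass through unchanged; the resulting table has one rest and at most
    one task row per channel.
    """
    meta = [c for c in META_COLUMNS if c != "task_name"]
    reduced = (
        features.groupby(meta, dropna=False)[FEATURE_NAMES]
        .mean()
        .reset_index()
    )
    reduced["task_name"] = np.where(reduced["condition"] == "task", "grouped", None)
    return reduced[META_COLUMNS + FEATURE_NAMES]


def per_hippocampus_reduce(features: pd.DataFrame) -> pd.DataFrame:
    """One vector per hippocampus: element-wise median over its channels.

    For an even channel count the median is the mean of the two central
    values (numpy convention). Metadata keeps the hippocampus identity;
    ``channel_id`` is replaced by the hippocampus id.
    """
    meta = ["subject_id", "hippocampus_id", "label", "condition", "task_name"]
    reduced = (
        features.groupby(meta, dropna=False)[FEATURE_NAMES]
        .median()
        .reset_index()
    )
    reduced["channel_id"] = reduced["hippocampus_id"]
    return reduced[META_COLUMNS + FEATURE_NAMES]
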