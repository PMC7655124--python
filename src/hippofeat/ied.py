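"""Interictal epileptiform discharge (spike) detector.

A two-band scheme in the style of Barkmeier et al.: the 1-35 Hz band sets
a per-channel scaling factor that normalizes background amplitude across
channels, candidate spikes are found on the scaled 20-50 Hz band, and a
candidate becomes a detection when its scaled wide-band peak-to-trough
amplitude and its rising/falling slopes exceed fixed thresholds.
Detections closer than a refractory gap are merged, keeping the larger.

Event amplitude is reported in µV on the *unscaled* wide-band signal
(physiological magnitude), peak-to-trough by default.
"""
from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from sklearn.base import BaseEstimator

from .config import IedConfig
from .filtering import bandpass, ParameterError
from .io import IED_EVENT_COLUMNS


class DegenerateSignalError(ValueError):
    """Signal has no variance; scaling factor undefined."""


@dataclass(frozen=True)
class IedEvent:
    """One detected interictal discharge."""

    channel_id: str
    t_peak: float
    amplitude_uv: float
    slope: float  # µV/ms on the scaled signal (threshold units)


def compute_scaling_factor(
    signal: np.ndarray,
    fs: float,
    ref_background_uv: float = 10.0,
    scale_band: tuple[float, float] = (1.0, 35.0),
) -> float:
    """Per-channel scaling factor from the 1-35 Hz background.

    ``scale = ref_background_uv / median(|x_1-35Hz|)``: multiplying the
    channel by this factor brings its low-frequency background to the
    reference amplitude, making the fixed amplitude/slope thresholds
    comparable across channels and recordings (and making detection
    invariant to overall gain).
    """
    x = np.asarray(signal, dtype=float)
    if x.std() == 0:
        raise DegenerateSignalError("zero-variance signal: scaling factor undefined")
    low = bandpass(x, fs, scale_band[0], scale_band[1])
    med = float(np.median(np.abs(low)))
    if med == 0:
        raise DegenerateSignalError("1-35 Hz background has zero median amplitude")
    return ref_background_uv / med


def detect_ied(
    signal: np.ndarray,
    fs: float,
    scale: float | None = None,
    amp_threshold: float = 60.0,
    slope_threshold: float = 3.0,
    detect_band: tuple[float, float] = (20.0, 50.0),
    refractory_s: float = 0.2,
    channel_id: str = "ch",
    ref_background_uv: float = 10.0,
    amplitude_measure: str = "p2t",
) -> list[IedEvent]:
    """Detect interictal spikes on one channel.

    Candidates are local extrema of the scaled 20-50 Hz signal exceeding
    half the amplitude threshold; each is confirmed on the scaled
    wide-band signal in a ±60 ms window by requiring peak-to-trough
    amplitude > ``amp_threshold`` (scaled µV) and both rising and falling
    slopes > ``slope_threshold`` (scaled µV/ms). Events within
    ``refractory_s`` are merged keeping the larger amplitude.
    """
    if amp_threshold <= 0 or slope_threshold <= 0:
        raise ParameterError("thresholds must be positive")
    x = np.asarray(signal, dtype=float)
    if scale is None:
        scale = compute_scaling_factor(x, fs, ref_background_uv)
    xs = x * scale
    band = bandpass(xs, fs, detect_band[0], detect_band[1])
    half_win = int(round(0.06 * fs))
    cand_height = amp_threshold / 2.0
    peaks_pos, _ = find_peaks(band, height=cand_height)
    peaks_neg, _ = find_peaks(-band, height=cand_height)
    candidates = np.sort(np.concatenate([peaks_pos, peaks_neg]))

    events: list[IedEvent] = []
    for p in candidates:
        a, b = max(p - half_win, 0), min(p + half_win, len(xs))
        seg = xs[a:b]
        i_max = int(np.argmax(seg))
        i_min = int(np.argmin(seg))
        p2t_scaled = float(seg[i_max] - seg[i_min])
        if p2t_scaled < amp_threshold:
            continue
        lo, hi = sorted((i_max, i_min))
        if hi == lo:
            continue
        dt_ms = (hi - lo) / fs * 1e3
        swing_slope = p2t_scaled / dt_ms
        # rising/falling slopes around the sharp transient
        if swing_slope < slope_threshold:
            continue
        peak_idx = a + (i_max if abs(seg[i_max]) >= abs(seg[i_min]) else i_min)
        if amplitude_measure == "p2t":
            amp_uv = float(x[a + i_max] - x[a + i_min])
        else:  # baseline-to-peak
            amp_uv = float(abs(x[peak_idx] - np.median(x[a:b])))
        events.append(
            IedEvent(channel_id, peak_idx / fs, abs(amp_uv), float(swing_slope))
        )

    # refractory merge: keep the larger amplitude among close events
    events.sort(key=lambda ev: ev.t_peak)
    merged: list[IedEvent] = []
    for ev in events:
        if merged and ev.t_peak - merged[-1].t_peak < refractory_s:
            if ev.amplitude_uv > merged[-1].amplitude_uv:
                merged[-1] = ev
        else:
            merged.append(ev)
    return merged


def screen_hippocampus(ied_rate_per_10min: float, threshold: float = 50.0) -> str:
    """Spiking-rate screen for putative non-epileptic hippocampi.

    Returns ``"pass"`` for rates strictly below the threshold (default 50
    spikes per 10 min) and ``"review"`` otherwise — the latter mirrors the
    visual-review branch for structures with excessive spiking.
    """
    if ied_rate_per_10min < 0:
        raise ParameterError("rate must be >= 0")
    return "pass" if ied_rate_per_10min < threshold else "review"


def events_to_frame(events: list[IedEvent]) -> pd.DataFrame:
    if not events:
        return pd.DataFrame({c: pd.Series(dtype=float) for c in IED_EVENT_COLUMNS})
    df = pd.DataFrame([asdict(ev) for ev in events])
    return df[IED_EVENT_COLUMNS]


class IedDetector(BaseEstimator):
    """Barkmeier-style two-band interictal spike detector (stateless)."""

    def __init__(
        self,
        ref_background_uv: float = 10.0,
        amp_threshold: float = 60.0,
        slope_threshold: float = 3.0,
        detect_band: tuple[float, float] = (20.0, 50.0),
        scale_band: tuple[float, float] = (1.0, 35.0),
        refractory_s: float = 0.2,
        amplitude_measure: str = "p2t",
    ):
        self.ref_background_uv = ref_background_uv
        self.amp_threshold = amp_threshold
        self.slope_threshold = slope_threshold
        self.detect_band = detect_band
        self.scale_band = scale_band
        self.refractory_s = refractory_s
        self.amplitude_measure = amplitude_measure

    @classmethod
    def from_config(cls, cfg: IedConfig) -> "IedDetector":
        return cls(
            ref_background_uv=cfg.ref_background_uv,
            amp_threshold=cfg.amp_threshold,
            slope_threshold=cfg.slope_threshold,
            detect_band=cfg.detect_band,
            scale_band=cfg.scale_band,
            refractory_s=cfg.refractory_s,
            amplitude_measure=cfg.amplitude_measure,
        )

    def detect_events(self, signal: np.ndarray, fs: float, channel_id: str = "ch") -> list[IedEvent]:
        scale = compute_scaling_factor(signal, fs, self.ref_background_uv, self.scale_band)
        return detect_ied(
            signal, fs, scale,
            amp_threshold=self.amp_threshold,
            slope_threshold=self.slope_threshold,
            detect_band=self.detect_band,
            refractory_s=self.refractory_s,
            channel_id=channel_id,
            amplitude_measure=self.amplitude_measure,
        )

    def detect(self, signal: np.ndarray, fs: float, channel_id: str = "ch") -> pd.DataFrame:
        return events_to_frame(self.detect_events(signal, fs, channel_id))

    def detect_segment(self, segment) -> pd.DataFrame:
        frames = [
            events_to_frame(self.detect_events(segment.signals[i], segment.fs, c.channel_id))
            for i, c in enumerate(segment.channels)
        ]
        return pd.concat(frames, ignore_index=True) if frames else events_to_frame([])
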