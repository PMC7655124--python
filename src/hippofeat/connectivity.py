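"""High-frequency functional connectivity between adjacent contacts.

Signals of adjacent hippocampal contacts are band-passed into the ripple
(80-250 Hz) and fast-ripple (250-600 Hz) bands, split into non-overlapping
1-s windows, and two per-window metrics are computed for each adjacent
pair: the Pearson linear correlation and the relative entropy
(Kullback-Leibler divergence) between the two windows' amplitude-sample
histograms. The per-channel connectivity feature is the mean over all
windows of all pairs that include the channel.

Relative entropy is directed; the per-pair per-window value used for
features is the symmetrized mean of REN(x,y) and REN(y,x) so the result
does not depend on contact ordering (both directed values are retained in
the long-format output).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .config import ConnectivityConfig
from .filtering import bandpass, ParameterError
from .io import RecordingSegment


class UndefinedMetricError(ValueError):
    """Metric undefined for this window (constant input or degenerate range)."""


def linear_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson product-moment correlation cov(X,Y)/(std(X) std(Y))."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ParameterError("inputs must have equal length >= 2")
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        raise UndefinedMetricError("correlation undefined for constant input")
    return float(np.clip(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy), -1.0, 1.0))


def relative_entropy(x: np.ndarray, y: np.ndarray, n_bins: int = 10, base: str = "e") -> float:
    """Kullback-Leibler divergence sum(pX log(pX/pY)) of two sample windows.

    pX and pY are histogram probability estimates over shared equal-width
    bins spanning the pooled range of both windows. Additive smoothing
    with epsilon = 1/(n_samples * n_bins) on both probability vectors
    keeps the divergence finite when a bin is empty under Y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ParameterError("inputs must have equal length")
    if n_bins < 2:
        raise ParameterError("n_bins must be >= 2")
    lo = min(x.min(), y.min())
    hi = max(x.max(), y.max())
    if lo == hi:
        raise UndefinedMetricError("degenerate pooled range: all samples equal")
    edges = np.linspace(lo, hi, n_bins + 1)
    px = np.histogram(x, bins=edges)[0] / x.size
    py = np.histogram(y, bins=edges)[0] / y.size
    eps = 1.0 / (x.size * n_bins)
    px = (px + eps) / (1.0 + eps * n_bins)
    py = (py + eps) / (1.0 + eps * n_bins)
    log = np.log2 if base == "2" else np.log
    return float(np.sum(px * log(px / py)))


@dataclass
class PairConnectivitySeries:
    """Per-window connectivity metrics for one adjacent contact pair/band."""

    pair: tuple[str, str]
    band: str  # 'R' or 'FR'
    window_s: float
    corr: np.ndarray
    ren_xy: np.ndarray
    ren_yx: np.ndarray

    @property
    def ren(self) -> np.ndarray:
        """Symmetrized relative entropy (mean of the two directions)."""
        return 0.5 * (self.ren_xy + self.ren_yx)


def adjacent_pairs(segment: RecordingSegment) -> list[tuple[int, int]]:
    """Index pairs of adjacent contacts (consecutive contact_index on one
    electrode), restricted to this segment's channels."""
    order: dict[str, list[tuple[int, int]]] = {}
    for i, c in enumerate(segment.channels):
        order.setdefault(c.electrode_id, []).append((c.contact_index, i))
    pairs = []
    for contacts in order.values():
        contacts.sort()
        for (ka, ia), (kb, ib) in zip(contacts, contacts[1:]):
            if kb == ka + 1:
                pairs.append((ia, ib))
    return pairs


def windowed_connectivity(
    segment: RecordingSegment,
    bands: dict[str, tuple[float, float]] | None = None,
    window_s: float = 1.0,
    n_bins: int = 10,
    log_base: str = "e",
) -> list[PairConnectivitySeries]:
    """Both connectivity metrics per 1-s window per adjacent pair per band.

    Windows where a metric is undefined (constant input) are recorded as
    NaN and skipped in summaries. A segment with fewer than two contacts
    on any electrode yields an empty result.
    """
    bands = bands or {"R": (80.0, 250.0), "FR": (250.0, 600.0)}
    pairs = adjacent_pairs(segment)
    if not pairs:
        return []
    w = int(round(window_s * segment.fs))
    n_win = segment.n_samples // w
    out: list[PairConnectivitySeries] = []
    for band_name, (f_lo, f_hi) in bands.items():
        filtered = bandpass(segment.signals, segment.fs, f_lo, f_hi, axis=-1)
        for ia, ib in pairs:
            xa, xb = filtered[ia], filtered[ib]
            corr = np.full(n_win, np.nan)
            ren_xy = np.full(n_win, np.nan)
            ren_yx = np.full(n_win, np.nan)
            for k in range(n_win):
                sl = slice(k * w, (k + 1) * w)
                try:
                    corr[k] = linear_correlation(xa[sl], xb[sl])
                except UndefinedMetricError:
                    pass
                try:
                    ren_xy[k] = relative_entropy(xa[sl], xb[sl], n_bins, log_base)
                    ren_yx[k] = relative_entropy(xb[sl], xa[sl], n_bins, log_base)
                except UndefinedMetricError:
                    pass
            out.append(
                PairConnectivitySeries(
                    pair=(segment.channels[ia].channel_id, segment.channels[ib].channel_id),
                    band=band_name,
                    window_s=window_s,
                    corr=corr,
                    ren_xy=ren_xy,
                    ren_yx=ren_yx,
                )
            )
    return out


def channel_connectivity_summary(series_list: list[PairConnectivitySeries]) -> pd.DataFrame:
    """Per-channel mean correlation and mean (symmetrized) relative entropy.

    A channel's value in a band is the mean over all windows of all pairs
    that include it; NaN windows are excluded.
    """
    rows: dict[tuple[str, str], dict[str, list[np.ndarray]]] = {}
    for s in series_list:
        for ch in s.pair:
            d = rows.setdefault((ch, s.band), {"corr": [], "ren": []})
            d["corr"].append(s.corr)
            d["ren"].append(s.ren)
    records = []
    for (ch, band), d in rows.items():
        corr = np.concatenate(d["corr"])
        ren = np.concatenate(d["ren"])
        records.append(
            {
                "channel_id": ch,
                "band": band,
                "corr": float(np.nanmean(corr)) if np.isfinite(corr).any() else np.nan,
                "ren": float(np.nanmean(ren)) if np.isfinite(ren).any() else np.nan,
            }
        )
    return pd.DataFrame(records, columns=["channel_id", "band", "corr", "ren"])


def series_to_frame(series_list: list[PairConnectivitySeries]) -> pd.DataFrame:
    """Long-format per-window table (pair, band, window_index, corr, ren_xy, ren_yx)."""
    frames = []
    for s in series_list:
        frames.append(
            pd.DataFrame(
                {
                    "channel_a": s.pair[0],
                    "channel_b": s.pair[1],
                    "band": s.band,
                    "window_index": np.arange(len(s.corr)),
                    "corr": s.corr,
                    "ren_xy": s.ren_xy,
                    "ren_yx": s.ren_yx,
                }
            )
        )
    cols = ["channel_a", "channel_b", "band", "window_index", "corr", "ren_xy", "ren_yx"]
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=cols)


class ConnectivityExtractor(BaseEstimator):
    """Windowed adjacent-pair connectivity extractor (stateless transform)."""

    def __init__(self, window_s: float = 1.0, n_bins: int = 10, log_base: str = "e"):
        self.window_s = window_s
        self.n_bins = n_bins
        self.log_base = log_base

    @classmethod
    def from_config(cls, cfg: ConnectivityConfig) -> "ConnectivityExtractor":
        return cls(window_s=cfg.window_s, n_bins=cfg.n_bins, log_base=cfg.log_base)

    def transform(self, segment: RecordingSegment) -> list[PairConnectivitySeries]:
        return windowed_connectivity(
            segment, window_s=self.window_s, n_bins=self.n_bins, log_base=self.log_base
        )

    def summary(self, segment: RecordingSegment) -> pd.DataFrame:
        return channel_connectivity_summary(self.transform(segment))
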