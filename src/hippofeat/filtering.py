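"""Shared zero-phase filtering utilities.

All band-pass filtering in the pipeline is zero-phase (forward-backward
Butterworth), so detected event latencies are not biased by filter group
delay.
"""
from __future__ import annotations

import numpy as np
from scipy import signal as sps


class ParameterError(ValueError):
    """Filter parameters outside the valid range."""


def bandpass(
    x: np.ndarray,
    fs: float,
    f_lo: float,
    f_hi: float,
    order: int = 4,
    axis: int = -1,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass.

    Parameters
    ----------
    x : array
        Signal (last axis = time unless ``axis`` given).
    fs : float
        Sampling rate in Hz.
    f_lo, f_hi : float
        Pass-band edges in Hz; must satisfy ``0 < f_lo < f_hi < fs/2``.
    order : int
        Butterworth order of the one-way filter; the forward-backward pass
        squares the magnitude response.

    Returns
    -------
    array of the same shape as ``x``.
    """
    if not (0 < f_lo < f_hi < fs / 2):
        raise ParameterError(
            f"band ({f_lo}, {f_hi}) Hz invalid for fs={fs} Hz (Nyquist {fs / 2})"
        )
    sos = sps.butter(order, (f_lo, f_hi), btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=axis)


def common_average_reference(signals: np.ndarray) -> np.ndarray:
    """Re-reference a channels x time array to the common average.

    Off by default in the pipeline: recordings are assumed already
    referenced (typically to the average of all intracranial contacts at
    acquisition time).
    """
    signals = np.asarray(signals, dtype=float)
    if signals.ndim != 2:
        raise ParameterError("expected a 2-D channels x time array")
    return signals - signals.mean(axis=0, keepdims=True)
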