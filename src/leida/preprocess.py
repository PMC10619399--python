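"""Temporal preprocessing of ROI time series.

Only the temporal steps of a resting-state pipeline are implemented here —
initial-volume discard (T2* equilibration), linear detrend, zero-phase
band-pass filtering and demeaning.  Image-space steps (registration,
smoothing, ICA denoising, nuisance regression) are assumed to have happened
before parcellation and are out of scope.

The band-pass is a 2nd-order Butterworth applied forward-backward
(``sosfiltfilt``), i.e. zero phase: downstream phase estimates must not be
distorted by filter delay.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sp_signal

from .data import RoiTimeSeries

DEFAULT_BAND = (0.01, 0.1)


def discard_initial_volumes(ts: RoiTimeSeries, n_discard: int) -> RoiTimeSeries:
    """Drop the first ``n_discard`` frames (scanner equilibration volumes)."""
    if n_discard < 0:
        raise ValueError("n_discard must be non-negative")
    if n_discard >= ts.n_frames:
        raise ValueError(
            f"cannot discard {n_discard} of {ts.n_frames} frames: nothing left"
        )
    if n_discard == 0:
        return ts
    return ts.with_data(ts.data[n_discard:])


def bandpass_detrend(
    ts: RoiTimeSeries,
    low: float = DEFAULT_BAND[0],
    high: float = DEFAULT_BAND[1],
    order: int = 2,
) -> RoiTimeSeries:
    """Linear detrend then zero-phase Butterworth band-pass, per region.

    ``low``/``high`` are in Hz and must satisfy 0 < low < high < Nyquist
    (= 1 / (2 TR)).  Detrending first removes the linear drift that a
    band-pass alone only attenuates on short records.
    """
    nyquist = 0.5 / ts.tr
    if not (0 < low < high):
        raise ValueError("need 0 < low < high")
    if high >= nyquist:
        raise ValueError(
            f"high cutoff {high} Hz must be below the Nyquist frequency "
            f"{nyquist} Hz at TR={ts.tr}s"
        )
    detrended = sp_signal.detrend(ts.data, axis=0, type="linear")
    sos = sp_signal.butter(order, [low, high], btype="bandpass", fs=1.0 / ts.tr, output="sos")
    filtered = sp_signal.sosfiltfilt(sos, detrended, axis=0)
    return ts.with_data(filtered)


def demean(ts: RoiTimeSeries) -> RoiTimeSeries:
    """Remove each region's temporal mean (required before the Hilbert step)."""
    return ts.with_data(ts.data - ts.data.mean(axis=0, keepdims=True))


def preprocess_scan(
    ts: RoiTimeSeries,
    n_discard: int = 0,
    low: float = DEFAULT_BAND[0],
    high: float = DEFAULT_BAND[1],
) -> RoiTimeSeries:
    """Full temporal pipeline: discard -> detrend/band-pass -> demean."""
    out = discard_initial_volumes(ts, n_discard)
    out = bandpass_detrend(out, low, high)
    return demean(out)
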