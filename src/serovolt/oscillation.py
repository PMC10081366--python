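"""Slow ambient-serotonin oscillation analysis.

Hippocampal basal serotonin oscillates with a period of roughly 6-10
minutes.  This module characterises those fluctuations in minute-resolution
FSCAV series: a 3rd-order Butterworth bandpass (0.0008-0.005 Hz, removing
both slow drug-driven drifts and measurement noise), lagged autocorrelation

    r_p = sum_{i=1}^{N-p} (X_i - Xbar)(X_{i+p} - Xbar) / sum_i (X_i - Xbar)^2,

sliding-window Pearson correlation between a window starting at t and the
same-length window lagged by p, Welch power spectral density, and the
power-weighted mean frequency

    WF = sum_i f_i * P_norm_i,

a scalar displacement measure of the whole spectrum.  Faster post-drug
oscillations (positive WF shift) indicate Uptake 1 (SERT) inhibition - the
high-capacity Uptake 2 route dominates and cycles faster; slower
oscillations (negative shift) indicate Uptake 2 inhibition.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .datatypes import FSCAVSeries, ValidationError

__all__ = [
    "PSDResult", "bandpass", "autocorrelation", "sliding_window_correlation",
    "welch_psd", "weighted_frequency", "compare_pre_post",
    "BAND_LOW_HZ", "BAND_HIGH_HZ",
]

logger = logging.getLogger(__name__)

BAND_LOW_HZ = 0.0008
BAND_HIGH_HZ = 0.005
BUTTER_ORDER = 3
#: Sliding-window correlation window length (minutes).
SWC_WINDOW_MIN = 25.0


def bandpass(series: FSCAVSeries, *, low_hz: float = BAND_LOW_HZ,
             high_hz: float = BAND_HIGH_HZ,
             order: int = BUTTER_ORDER) -> FSCAVSeries:
    """Zero-phase 3rd-order Butterworth bandpass of a basal series.

    Applied forward-backward (sosfiltfilt), so the effective magnitude
    response is the squared 3rd-order Butterworth and the phase is zero.
    DC is rejected; the output mean is ~0.  Series shorter than about three
    periods of the low cutoff only trigger a warning.
    """
    x = series.concentration_nM
    fs = 1.0 / series.sampling_period_s
    if series.time_min.size >= 2:
        steps = np.diff(series.time_min)
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
            raise ValidationError("bandpass requires uniform sampling")
    min_len_s = 3.0 / low_hz
    if x.size * series.sampling_period_s < min_len_s:
        warnings.warn(
            f"series shorter than ~{min_len_s / 60:.0f} min; bandpass output "
            "is poorly resolved at the low cutoff", stacklevel=2)
    sos = sps.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs,
                     output="sos")
    padlen = min(x.size - 2, 3 * 6 * order)
    filtered = sps.sosfiltfilt(sos, x - x.mean(), padlen=max(padlen, 0))
    return FSCAVSeries(series.time_min.copy(), filtered,
                       metadata={**series.metadata, "bandpassed": True,
                                 "band_hz": (low_hz, high_hz)})


def autocorrelation(series: FSCAVSeries, max_lag: int) -> np.ndarray:
    """Lagged autocorrelation r_p for p = 0..max_lag.

    Uses the full-series mean and the full-series variance in the
    denominator; r_0 = 1 exactly.
    """
    x = series.concentration_nM
    n = x.size
    if not 0 <= max_lag < n:
        raise ValidationError("max_lag must satisfy 0 <= max_lag < length")
    xc = x - x.mean()
    denom = float(np.sum(xc * xc))
    if denom == 0:
        raise ValidationError("zero-variance series: correlation undefined")
    r = np.empty(max_lag + 1)
    for p in range(max_lag + 1):
        r[p] = np.sum(xc[: n - p] * xc[p:]) / denom
    return r


def sliding_window_correlation(series: FSCAVSeries,
                               lags: Sequence[int],
                               *, window_min: float = SWC_WINDOW_MIN
                               ) -> np.ndarray:
    """Pearson correlation between each window and its lagged copy.

    Returns a matrix of shape (number of valid window starts, number of
    lags); entry (t, p) correlates the window of ``window_min`` minutes
    starting at sample t with the window starting at t + lag.  Windows with
    zero variance yield NaN (an undefined marker, not an exception).
    """
    x = series.concentration_nM
    l = int(round(window_min * 60.0 / series.sampling_period_s))
    if l < 2:
        raise ValidationError("window too short at this sampling period")
    lags = np.asarray(list(lags), dtype=int)
    if lags.size == 0:
        raise ValidationError("no lags requested")
    max_lag = int(lags.max())
    n_starts = x.size - l + 1 - max_lag
    if n_starts < 1:
        raise ValidationError("window + max lag exceed the series span")
    out = np.empty((n_starts, lags.size))
    for ti in range(n_starts):
        w0 = x[ti: ti + l]
        s0 = w0.std()
        for pi, p in enumerate(lags):
            w1 = x[ti + p: ti + p + l]
            s1 = w1.std()
            if s0 == 0 or s1 == 0:
                out[ti, pi] = np.nan
                continue
            out[ti, pi] = float(np.corrcoef(w0, w1)[0, 1])
    return out


@dataclass
class PSDResult:
    """Welch power spectrum with normalised power and its WF summary."""

    frequencies_hz: np.ndarray
    power: np.ndarray
    normalized_power: np.ndarray
    weighted_frequency_hz: float


def welch_psd(series: FSCAVSeries, *, nperseg: int | None = None,
              window: str = "hann", detrend: str = "constant") -> PSDResult:
    """Welch power spectral density of a basal series.

    Defaults: segment length = half the series, 50% overlap, Hann window,
    constant detrend per segment.  Normalised power sums to 1.
    """
    x = series.concentration_nM
    if nperseg is None:
        nperseg = x.size // 2
    if nperseg < 2 or x.size < nperseg:
        raise ValidationError("series too short for Welch estimation")
    fs = 1.0 / series.sampling_period_s
    freqs, power = sps.welch(x, fs=fs, window=window, nperseg=nperseg,
                             noverlap=nperseg // 2, detrend=detrend)
    total = float(power.sum())
    if total == 0:
        raise ValidationError("all-zero power spectrum")
    norm = power / total
    return PSDResult(frequencies_hz=freqs, power=power, normalized_power=norm,
                     weighted_frequency_hz=float(np.sum(freqs * norm)))


def weighted_frequency(psd: PSDResult, *, normalized: bool = True) -> float:
    """Sum of power-weighted frequencies.

    With ``normalized=True`` (default) this is the normalised-power-weighted
    mean frequency, guaranteed to lie inside the frequency grid; the
    unnormalised sum(f * P) variant is available for spectra whose absolute
    power scale is meaningful.
    """
    if float(psd.power.sum()) == 0:
        raise ValidationError("all-zero power spectrum")
    weights = psd.normalized_power if normalized else psd.power
    return float(np.sum(psd.frequencies_hz * weights))


def compare_pre_post(pre_series: Sequence[FSCAVSeries],
                     post_series: Sequence[FSCAVSeries],
                     *, bandpass_first: bool = True,
                     normalized: bool = True) -> tuple[pd.DataFrame, dict]:
    """Per-animal pre/post weighted-frequency comparison.

    ``pre_series[i]`` and ``post_series[i]`` must belong to the same animal.
    Returns a table (animal, wf_pre_hz, wf_post_hz, delta_hz) and a group
    summary with the mean delta and its directional reading: a positive mean
    shift is Uptake-1-like (SERT inhibition), a negative one Uptake-2-like.
    """
    if len(pre_series) != len(post_series):
        raise ValidationError("pre and post series lists must be matched")
    if not pre_series:
        raise ValidationError("no animals supplied")
    rows = []
    for i, (pre, post) in enumerate(zip(pre_series, post_series)):
        if bandpass_first:
            pre, post = bandpass(pre), bandpass(post)
        wf_pre = weighted_frequency(welch_psd(pre), normalized=normalized)
        wf_post = weighted_frequency(welch_psd(post), normalized=normalized)
        rows.append({"animal": i, "wf_pre_hz": wf_pre, "wf_post_hz": wf_post,
                     "delta_hz": wf_post - wf_pre})
    table = pd.DataFrame(rows)
    mean_delta = float(table["delta_hz"].mean())
    if mean_delta > 0:
        direction = "uptake1-like"
    elif mean_delta < 0:
        direction = "uptake2-like"
    else:
        direction = "no-change"
    summary = {"mean_delta_hz": mean_delta,
               "n_positive": int((table["delta_hz"] > 0).sum()),
               "n_negative": int((table["delta_hz"] < 0).sum()),
               "direction": direction}
    return table, summary
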