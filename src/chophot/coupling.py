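"""Pupil–fluorescence coupling: coherence spectra and lead/lag estimation.

Fluorescence is first brought onto the pupil clock (nominally 30 Hz) with an
anti-aliasing FIR low-pass, then magnitude-squared coherence is estimated by
Welch averaging with a Hamming taper (1500-sample windows, 1400-sample
overlap) and the lead/lag from the peak of the per-lag Pearson
cross-correlation.  Positive lag means fluorescence LEADS pupil.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .traces import DffTrace, PupilTrace

__all__ = [
    "CoherenceResult",
    "LagResult",
    "resample_to_common",
    "coherence_spectrum",
    "estimate_lag",
]


@dataclass
class CoherenceResult:
    freqs: np.ndarray
    coherence: np.ndarray
    window_len: int
    overlap: int
    fs_common: float


@dataclass
class LagResult:
    lag_s: float
    lags_s: np.ndarray
    xcorr: np.ndarray
    max_lag_s: float
    tie: bool = False


def _detrend(x: np.ndarray, linear: bool) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if linear:
        return sps.detrend(x, type="linear")
    return x - x.mean()


def resample_to_common(
    fluo: DffTrace, pupil: PupilTrace, fs_common: float = 30.0
) -> tuple[np.ndarray, np.ndarray, float]:
    """Anti-alias and evaluate fluorescence at pupil frame times.

    The fluorescence trace is zero-phase FIR low-passed with a cutoff 80% of
    the common Nyquist (stopband from the Nyquist on, >40 dB down after the
    forward-backward pass) and linearly interpolated at the pupil frame
    times; both series are restricted to the overlapping support.

    Returns ``(fluo_common, pupil_common, fs_common)`` of equal length.

    Raises
    ------
    ValueError
        If the overlapping support is shorter than 60 s.
    """
    tf = fluo.times
    tp = pupil.times
    t_start = max(tf[0], tp[0])
    t_end = min(tf[-1], tp[-1])
    if t_end - t_start < 60.0:
        raise ValueError("need at least 60 s of overlapping support")

    x = np.asarray(fluo.dff, dtype=float)
    nyq_common = fs_common / 2.0
    if fluo.fs > fs_common:
        # Kaiser FIR: passband to 0.65 x common Nyquist, full stopband
        # attenuation from 0.9 x Nyquist on (well below the Nyquist itself)
        width = 0.25 * nyq_common
        ripple_db = 65.0
        numtaps, beta = sps.kaiserord(ripple_db, width / (fluo.fs / 2.0))
        numtaps |= 1  # odd taps -> symmetric, integer group delay
        taps = sps.firwin(
            numtaps, 0.775 * nyq_common, window=("kaiser", beta), fs=fluo.fs
        )
        if numtaps < len(x):
            x = sps.filtfilt(taps, [1.0], x, padtype="even", padlen=numtaps - 1)

    keep_p = (tp >= t_start - 1e-9) & (tp <= t_end + 1e-9)
    tq = tp[keep_p]
    fluo_common = np.interp(tq, tf, x)
    pupil_common = np.asarray(pupil.diameter, dtype=float)[keep_p]
    return fluo_common, pupil_common, fs_common


def coherence_spectrum(
    x: np.ndarray,
    y: np.ndarray,
    fs: float,
    window_len: int = 1500,
    overlap: int = 1400,
    detrend_linear: bool = True,
) -> CoherenceResult:
    """Welch magnitude-squared coherence |Pxy|²/(Pxx·Pyy), Hamming taper.

    FFT length equals ``window_len`` (no zero padding).  Series are
    detrended (linear by default, mean-only if disabled) before estimation;
    scipy additionally removes the per-segment mean.

    Raises
    ------
    ValueError
        If fewer than two segments fit or ``overlap >= window_len``.
    """
    x = _detrend(x, detrend_linear)
    y = _detrend(y, detrend_linear)
    if x.shape != y.shape:
        raise ValueError("series must have equal length")
    if overlap >= window_len:
        raise ValueError("overlap must be smaller than window_len")
    if len(x) < 2 * window_len:
        raise ValueError("series too short: need at least two full windows")
    freqs, coh = sps.coherence(
        x,
        y,
        fs=fs,
        window="hamming",
        nperseg=window_len,
        noverlap=overlap,
        nfft=window_len,
        detrend="constant",
    )
    return CoherenceResult(
        freqs=freqs,
        coherence=np.clip(coh, 0.0, 1.0),
        window_len=window_len,
        overlap=overlap,
        fs_common=fs,
    )


def estimate_lag(
    x: np.ndarray,
    y: np.ndarray,
    fs: float,
    max_lag_s: float = 5.0,
    detrend_linear: bool = True,
) -> LagResult:
    """Lead/lag from the peak of the per-lag Pearson cross-correlation.

    For each integer lag k in ``[-max_lag_s, +max_lag_s]`` the Pearson
    correlation between the overlapping segments of x and y (y shifted later
    by k samples) is computed.  The reported lag maximizes the correlation;
    positive lag means x (fluorescence) leads y (pupil).  When several lags
    tie for the global maximum, the smallest |lag| is returned and flagged.

    Raises
    ------
    ValueError
        If either series has zero variance.
    """
    x = _detrend(np.asarray(x, float), detrend_linear)
    y = _detrend(np.asarray(y, float), detrend_linear)
    if x.shape != y.shape:
        raise ValueError("series must have equal length")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input")
    n = len(x)
    L = int(round(max_lag_s * fs))
    if L >= n - 1:
        raise ValueError("max_lag_s too large for the series length")

    lags = np.arange(-L, L + 1)
    corr = np.empty(lags.size)
    for i, k in enumerate(lags):
        if k >= 0:
            a, b = x[: n - k], y[k:]
        else:
            a, b = x[-k:], y[: n + k]
        sa, sb = a.std(), b.std()
        corr[i] = 0.0 if sa == 0 or sb == 0 else float(
            np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb)
        )

    cmax = corr.max()
    at_max = np.flatnonzero(corr >= cmax - 1e-12)
    tie = at_max.size > 1
    # smallest |lag| wins; a symmetric +/-tau tie resolves to the positive lag
    best = min(at_max, key=lambda i: (abs(int(lags[i])), -int(lags[i])))
    return LagResult(
        lag_s=float(lags[best] / fs),
        lags_s=lags / fs,
        xcorr=corr,
        max_lag_s=max_lag_s,
        tie=tie,
    )
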