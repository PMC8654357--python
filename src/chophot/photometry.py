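"""Fluorescence preprocessing: ΔF/F₀, zero-lag low-pass, baseline z-score.

The processing chain converts raw demodulated fluorescence to a z-scored
fractional change signal in three fixed steps:

1. ``compute_dff`` — ΔF/F₀ against a 60 s running-median baseline F₀,
2. ``lowpass_zero_lag`` — second-order zero-phase Butterworth low-pass (7 Hz),
3. ``zscore_to_baseline`` — z-score against pooled pre-stimulus windows.

The running-median window is centered by default and shrinks (truncates) at
the trace edges rather than padding, so no data are invented at the ends.
A trailing window is available for causal use.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal

from .traces import DffTrace, FluorescenceTrace

__all__ = [
    "running_median",
    "compute_dff",
    "lowpass_zero_lag",
    "zscore_to_baseline",
    "unzscore",
    "preprocess",
]


def running_median(values: np.ndarray, window: int, mode: str = "centered") -> np.ndarray:
    """Running median with edge-truncated windows.

    Parameters
    ----------
    values : ndarray
        Input samples.
    window : int
        Window length in samples.  For ``mode="centered"`` an even window is
        widened to the next odd count so the window is symmetric.
    mode : {"centered", "trailing"}
        Window placement relative to the output sample.
    """
    values = np.asarray(values, dtype=float)
    if window < 1:
        raise ValueError("window must be >= 1 sample")
    s = pd.Series(values)
    if mode == "centered":
        if window % 2 == 0:
            window += 1
        out = s.rolling(window, center=True, min_periods=1).median()
    elif mode == "trailing":
        out = s.rolling(window, center=False, min_periods=1).median()
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return out.to_numpy()


def median_window_samples(fs: float, window_s: float) -> int:
    """Centered running-median window length in samples: ``2*floor(w*fs/2)+1``."""
    return 2 * int(np.floor(window_s * fs / 2)) + 1


def compute_dff(
    trace: FluorescenceTrace,
    window_s: float = 60.0,
    channel: str = "465",
    mode: str = "centered",
) -> DffTrace:
    """ΔF/F₀ with F₀ a running median over ``window_s`` seconds.

    ``dff[i] = (F[i] - F0[i]) / F0[i]`` where ``F0[i]`` is the median of F
    over the window centered at i (truncated at the edges).  Output is
    neither filtered nor z-scored.

    Raises
    ------
    ValueError
        If the trace is too short, the window non-positive, or any baseline
        value is ≤ 0 (division guard).
    """
    if len(trace) < 2:
        raise ValueError("trace must contain more than one sample")
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    F = trace.values_465 if channel == "465" else trace.values_405
    if F is None:
        raise ValueError(f"channel {channel!r} not present in trace")
    w = median_window_samples(trace.fs, window_s) if mode == "centered" else max(
        int(round(window_s * trace.fs)), 1
    )
    F0 = running_median(F, w, mode=mode)
    if np.any(F0 <= 0):
        raise ValueError("running-median baseline is non-positive; cannot form dF/F0")
    return DffTrace(fs=trace.fs, dff=(F - F0) / F0, t0=trace.t0, fiber_id=trace.fiber_id)


def lowpass_zero_lag(trace: DffTrace, cutoff_hz: float = 7.0, order: int = 2) -> DffTrace:
    """Zero-phase Butterworth low-pass (forward-backward filtering).

    Two passes square the magnitude response, so a pure sinusoid at the
    corner frequency comes out at half its input amplitude.  Edges are
    handled by reflective padding at least three times the nominal impulse
    response length (``3·fs/cutoff`` samples) so startup transients do not
    leak into the trace.
    """
    nyq = trace.fs / 2
    if not 0 < cutoff_hz < nyq:
        raise ValueError(f"cutoff must lie in (0, Nyquist={nyq} Hz)")
    b, a = signal.butter(order, cutoff_hz, btype="low", fs=trace.fs)
    padlen = min(len(trace) - 1, max(int(3 * trace.fs / cutoff_hz), 3 * max(len(a), len(b))))
    out = signal.filtfilt(b, a, trace.dff, padtype="even", padlen=padlen)
    return trace.with_values(out)


def zscore_to_baseline(
    trace: DffTrace, baseline_windows: list[tuple[float, float]]
) -> DffTrace:
    """Z-score ΔF/F₀ against samples pooled over baseline windows.

    Windows are (start_s, end_s) in session time, half-open.  For passive
    sessions these are the 2 s pre-stimulus windows; for operant sessions the
    2 s pre-cue windows pooled across trial types and sessions.

    Raises
    ------
    ValueError
        On empty/out-of-range windows, pooled count < 2 or zero baseline SD.
    """
    if not baseline_windows:
        raise ValueError("baseline_windows must be non-empty")
    t_end = trace.t0 + len(trace) / trace.fs
    mask = np.zeros(len(trace), dtype=bool)
    for start, end in baseline_windows:
        if end <= start:
            raise ValueError(f"window ({start}, {end}) is empty")
        if start < trace.t0 - 1e-9 or end > t_end + 1e-9:
            raise ValueError(f"window ({start}, {end}) lies outside the trace")
        i0 = max(int(np.ceil((start - trace.t0) * trace.fs - 1e-9)), 0)
        i1 = min(int(np.ceil((end - trace.t0) * trace.fs - 1e-9)), len(trace))
        mask[i0:i1] = True
    pooled = trace.dff[mask]
    if pooled.size < 2:
        raise ValueError("pooled baseline must contain at least 2 samples")
    mu = float(np.mean(pooled))
    sd = float(np.std(pooled, ddof=0))
    if sd <= 100 * np.finfo(float).eps * max(1.0, abs(mu)):
        raise ValueError("degenerate baseline: zero standard deviation")
    return trace.with_values((trace.dff - mu) / sd, zscored=True, baseline_stats=(mu, sd))


def baseline_sample_mask(trace: DffTrace, baseline_windows) -> np.ndarray:
    """Boolean mask of samples pooled by :func:`zscore_to_baseline` (for QC)."""
    t_end = trace.t0 + len(trace) / trace.fs
    mask = np.zeros(len(trace), dtype=bool)
    for start, end in baseline_windows:
        i0 = max(int(np.ceil((start - trace.t0) * trace.fs - 1e-9)), 0)
        i1 = min(int(np.ceil((end - trace.t0) * trace.fs - 1e-9)), len(trace))
        mask[i0:i1] = True
    return mask


def unzscore(trace: DffTrace) -> DffTrace:
    """Invert :func:`zscore_to_baseline` using the stored baseline stats."""
    if not trace.zscored:
        return trace
    mu, sd = trace.baseline_stats
    return trace.with_values(trace.dff * sd + mu, zscored=False, baseline_stats=None)


def preprocess(
    trace: FluorescenceTrace,
    window_s: float = 60.0,
    cutoff_hz: float = 7.0,
    order: int = 2,
    baseline_windows: list[tuple[float, float]] | None = None,
) -> DffTrace:
    """Full chain: ΔF/F₀ → zero-lag low-pass → (optional) baseline z-score."""
    out = lowpass_zero_lag(compute_dff(trace, window_s=window_s), cutoff_hz=cutoff_hz, order=order)
    if baseline_windows is not None:
        out = zscore_to_baseline(out, baseline_windows)
    return out
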