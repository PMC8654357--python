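"""Event-locked response metrics, habituation curves, spontaneous transients.

Every figure-level quantity is expressed as an :class:`EventMetricConfig`
naming the alignment event, a baseline window/statistic and a response
window/statistic (windows in seconds relative to the alignment event,
half-open).  Two amplitude conventions coexist and are kept as distinct
named configs rather than reconciled:

* single-window: amplitude = response_stat − baseline_stat
  (tone-evoked and reinforcement responses, lick on/offset responses);
* post−pre: the baseline mean is subtracted from both a response-window peak
  and a short pre-onset peak, and amplitude = post − pre
  (passive sensory characterization).

"Peak" means the maximum (responses of interest are positive-going); peak
latency takes the earliest maximum on ties.  Events whose windows overlap a
trace edge are skipped, never zero-padded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .traces import DffTrace

__all__ = [
    "EventMetricConfig",
    "EventResponse",
    "NAMED_CONFIGS",
    "event_amplitude",
    "event_amplitudes",
    "habituation_curve",
    "habituation_slope",
    "spontaneous_transients",
    "session_time_bins",
    "display_smooth",
]


@dataclass
class EventMetricConfig:
    name: str
    align_to: str  # stim_onset | seventh_lick | bout_onset | bout_offset | reinforcement
    baseline_window: tuple[float, float]
    response_window: tuple[float, float]
    baseline_stat: str = "mean"  # mean | max
    response_stat: str = "peak"  # peak | mean
    pre_response_window: tuple[float, float] | None = None  # post-pre variant

    def __post_init__(self) -> None:
        for w in (self.baseline_window, self.response_window, self.pre_response_window):
            if w is not None and w[1] <= w[0]:
                raise ValueError(f"window {w} is empty or reversed")


#: Figure-legend metric definitions (windows relative to the alignment event).
NAMED_CONFIGS: dict[str, EventMetricConfig] = {
    # passive characterization: 2 s pre-stimulus mean subtracted from both the
    # stimulus-period peak and a 0.4 s pre-onset peak; amplitude = post - pre
    "sensory_passive": EventMetricConfig(
        "sensory_passive", "stim_onset", (-2.0, 0.0), (0.0, 2.0),
        baseline_stat="mean", response_stat="peak", pre_response_window=(-0.4, 0.0),
    ),
    # operant tone response: peak within 400 ms of onset minus 2 s pre mean
    "tone_operant": EventMetricConfig(
        "tone_operant", "stim_onset", (-2.0, 0.0), (0.0, 0.4),
    ),
    # mean activity in the 1 s preceding stimulus onset (pre-cue state)
    "baseline_1s": EventMetricConfig(
        "baseline_1s", "stim_onset", (-1.0, 0.0), (-1.0, 0.0),
        baseline_stat="mean", response_stat="mean",
    ),
    # lick bout onset: max in [-0.25, 0) vs max in [0, 0.7)
    "lick_onset": EventMetricConfig(
        "lick_onset", "bout_onset", (-0.25, 0.0), (0.0, 0.7),
        baseline_stat="max", response_stat="peak",
    ),
    # lick bout offset: max in [-0.4, 0) vs max in [0, 0.7)
    "lick_offset": EventMetricConfig(
        "lick_offset", "bout_offset", (-0.4, 0.0), (0.0, 0.7),
        baseline_stat="max", response_stat="peak",
    ),
    # reinforcement response: peak within 2 s after the 7th lick minus the
    # 2 s pre-stimulus mean (baseline aligned separately to the tone onset)
    "reinforcement": EventMetricConfig(
        "reinforcement", "seventh_lick", (-2.0, 0.0), (0.0, 2.0),
    ),
    # reinforcement latency: peak time within 2 s relative to 7th-lick offset
    "reinforcement_latency": EventMetricConfig(
        "reinforcement_latency", "seventh_lick", (-2.0, 0.0), (0.0, 2.0),
    ),
}


@dataclass
class EventResponse:
    event_s: float
    amplitude: float
    peak_latency_s: float
    name: str = ""


def _window_slice(trace: DffTrace, center_s: float, window: tuple[float, float]):
    i0 = int(np.ceil((center_s + window[0] - trace.t0) * trace.fs - 1e-9))
    i1 = int(np.ceil((center_s + window[1] - trace.t0) * trace.fs - 1e-9))
    if i0 < 0 or i1 > len(trace) or i1 <= i0:
        return None
    return i0, i1


def _stat(x: np.ndarray, which: str) -> float:
    if which in ("peak", "max"):
        return float(np.max(x))
    if which == "mean":
        return float(np.mean(x))
    raise ValueError(f"unknown statistic {which!r}")


def event_amplitude(
    trace: DffTrace,
    event_s: float,
    cfg: EventMetricConfig,
    baseline_event_s: float | None = None,
) -> EventResponse | None:
    """Amplitude and peak latency for one event under a metric config.

    ``baseline_event_s`` lets the baseline window align to a different event
    than the response (e.g. reinforcement responses baseline-aligned to tone
    onset); it defaults to ``event_s``.  Returns None (skipped) when any
    window falls outside the trace.
    """
    b_center = event_s if baseline_event_s is None else baseline_event_s
    bsl = _window_slice(trace, b_center, cfg.baseline_window)
    rsl = _window_slice(trace, event_s, cfg.response_window)
    if bsl is None or rsl is None:
        return None
    baseline = _stat(trace.dff[bsl[0] : bsl[1]], cfg.baseline_stat)
    resp_seg = trace.dff[rsl[0] : rsl[1]]
    response = _stat(resp_seg, cfg.response_stat)

    if cfg.pre_response_window is not None:
        psl = _window_slice(trace, event_s, cfg.pre_response_window)
        if psl is None:
            return None
        pre = _stat(trace.dff[psl[0] : psl[1]], "peak")
        amplitude = (response - baseline) - (pre - baseline)
    else:
        amplitude = response - baseline

    peak_idx = int(np.argmax(resp_seg))  # earliest maximum on ties
    latency = (rsl[0] + peak_idx) / trace.fs + trace.t0 - event_s
    return EventResponse(float(event_s), float(amplitude), float(latency), cfg.name)


def event_amplitudes(
    trace: DffTrace,
    events_s: np.ndarray,
    cfg: EventMetricConfig,
    baseline_events_s: np.ndarray | None = None,
) -> list[EventResponse]:
    """Vector version of :func:`event_amplitude`; edge-overlapping events skipped."""
    out = []
    for i, e in enumerate(np.asarray(events_s, dtype=float)):
        b = None if baseline_events_s is None else float(baseline_events_s[i])
        r = event_amplitude(trace, float(e), cfg, baseline_event_s=b)
        if r is not None:
            out.append(r)
    return out


def habituation_curve(
    amplitudes: np.ndarray, normalize: bool = True
) -> tuple[np.ndarray, bool]:
    """Per-presentation response amplitudes, normalized to the first.

    Returns ``(curve, normalized)``.  If the first amplitude is not positive
    the raw curve is returned with ``normalized=False`` instead of dividing
    by a non-positive reference.
    """
    amplitudes = np.asarray(amplitudes, dtype=float)
    if amplitudes.size < 2:
        raise ValueError("need at least two presentations")
    if not normalize:
        return amplitudes.copy(), False
    if amplitudes[0] <= 0:
        return amplitudes.copy(), False
    return amplitudes / amplitudes[0], True


def habituation_slope(amplitudes: np.ndarray, n_trials: int | float = 10) -> float:
    """OLS slope of amplitude vs presentation index over an early-trial span.

    ``n_trials`` is either an absolute count (first 10 trials) or a fraction
    of the session (first 20% of trials).  Units: response units per trial.
    """
    amplitudes = np.asarray(amplitudes, dtype=float)
    if 0 < n_trials < 1:
        span = int(np.ceil(n_trials * amplitudes.size))
    else:
        span = int(n_trials)
    if span > amplitudes.size:
        raise ValueError("fitted span exceeds the available trials")
    if span < 3:
        raise ValueError("need at least 3 trials in the fitted span")
    x = np.arange(span, dtype=float)
    return float(np.polyfit(x, amplitudes[:span], 1)[0])


def display_smooth(values: np.ndarray, kernel: int = 7) -> np.ndarray:
    """7-point median filter used for session displays only (never for fits)."""
    return ndimage.median_filter(np.asarray(values, float), size=kernel, mode="nearest")


def spontaneous_transients(
    trace: DffTrace,
    trial_window: tuple[float, float],
    offset: float = 0.5,
    percentile: float = 5.0,
) -> tuple[float, float, np.ndarray]:
    """Spontaneous-transient statistic within a stimulus-free trial window.

    The threshold τ is the ``percentile`` (bottom 5%) of in-window values;
    samples at least ``offset`` (0.5 z on the session z-score scale) above τ
    are suprathreshold, and the statistic is their mean.  Returns
    ``(threshold, mean_suprathreshold, mask)``; an empty mask yields NaN.
    """
    sl = _window_slice(trace, 0.0, trial_window)
    if sl is None:
        raise ValueError("trial window lies outside the trace")
    vals = trace.dff[sl[0] : sl[1]]
    if vals.size < 20:
        raise ValueError("trial window must contain at least 20 samples")
    tau = float(np.quantile(vals, percentile / 100.0))
    mask = vals >= tau + offset
    mean_supra = float(np.mean(vals[mask])) if mask.any() else float("nan")
    return tau, mean_supra, mask


def session_time_bins(n_sessions: int, n_bins: int = 5) -> np.ndarray:
    """Training-time bin per session: ``ceil(n_bins * fraction_completed)``.

    Sessions are chronological; session i of n has completed fraction i/n
    (1-based), so bins are 1..n_bins with later sessions never in an earlier
    bin than earlier sessions.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    i = np.arange(1, n_sessions + 1)
    return np.ceil(n_bins * i / n_sessions).astype(int)
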