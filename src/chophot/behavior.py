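"""Operant task parsing: trial scoring, aborts, lick bouts, learning curves.

Task structure: a tone (low/mid/high frequency) is presented and the mouse
must produce a vigorous lick bout — seven lickspout contacts within a 2.8 s
window beginning 0.2 s after tone onset, with no gap between consecutive
counted licks exceeding 1 s — to trigger reinforcement.  In Phase 1 every
tone is rewarded; in Phase 2 one tone stays rewarded while the other two
switch to reward omission and tongue shock.  Trials with a lick during the
pre-stimulus withhold period (2 s in Phase 1, 1.5 s in Phase 2) are aborted.

Scoring vocabulary: *hit* — criterion met; *miss* — no licks in the response
window; *partial hit* — licks present but criterion unmet; *go* — criterion
met regardless of the scheduled reinforcement.  Reinforcement (or the
virtual omission event) is timed to the seventh qualifying lick.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SessionEvents",
    "TrialRecord",
    "LickBout",
    "RESPONSE_WINDOW_START",
    "RESPONSE_WINDOW_END",
    "score_trial",
    "detect_abort",
    "score_session",
    "find_intertrial_bouts",
    "go_probability_curve",
    "bout_size_bin",
]

RESPONSE_WINDOW_START = 0.2  # s after tone onset
RESPONSE_WINDOW_END = 3.0  # s after tone onset (0.2 + 2.8, half-open)
HIT_LICK_COUNT = 7
MAX_INTERLICK_GAP = 1.0  # s, between consecutive counted licks
BOUT_MAX_GAP = 0.25  # s, strict: gaps must be < 250 ms
BOUT_QUIESCENCE = 1.0  # s, inclusive, both sides
WITHHOLD_S = {1: 2.0, 2: 1.5}


@dataclass
class TrialRecord:
    onset_s: float
    tone: str
    outcome: str  # hit | miss | partial_hit | aborted
    go: bool
    lick_count_in_window: int
    seventh_lick_s: float | None
    reinforcement_type: str = "none"  # reward | shock | omission | none
    phase: int = 1
    session_id: str = ""
    mouse_id: str = ""


@dataclass
class LickBout:
    start_s: float
    end_s: float
    n_licks: int
    size_bin: str


@dataclass
class SessionEvents:
    """Raw event streams for one session.

    ``stim_onsets`` rows are (onset_s, tone, phase); reinforcement rows are
    (time_s, type).  Timestamps must be non-decreasing within each stream.
    """

    stim_onsets: list[tuple[float, str, int]]
    licks: np.ndarray
    reinforcement: list[tuple[float, str]] = field(default_factory=list)
    session_id: str = ""
    mouse_id: str = ""

    def __post_init__(self) -> None:
        self.licks = np.asarray(self.licks, dtype=float)
        if np.any(np.diff(self.licks) < 0):
            raise ValueError("lick timestamps must be non-decreasing")
        onsets = [s[0] for s in self.stim_onsets]
        if any(b < a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("stimulus onsets must be non-decreasing")


def _check_sorted(licks: np.ndarray) -> np.ndarray:
    licks = np.asarray(licks, dtype=float)
    if np.any(np.diff(licks) < 0):
        raise ValueError("licks must be sorted")
    return licks


def bout_size_bin(n: int) -> str:
    if n <= 2:
        return "1-2"
    if n <= 4:
        return "3-4"
    if n <= 6:
        return "5-6"
    return "7+"


def score_trial(
    onset_s: float,
    licks: np.ndarray,
    phase: int = 1,
    tone: str = "",
    reinforcement_map: dict[str, str] | None = None,
) -> TrialRecord:
    """Score one trial from sorted lick timestamps.

    The response window is ``[onset+0.2, onset+3.0)``.  Hit requires at
    least seven licks in the window with every gap among the first seven
    counted licks at most 1 s; licks after the seventh are ignored for
    scoring.  ``reinforcement_map`` (tone → reward/shock/omission) assigns
    the outcome type on go trials; reinforcement time is the seventh lick.
    """
    licks = _check_sorted(licks)
    w0, w1 = onset_s + RESPONSE_WINDOW_START, onset_s + RESPONSE_WINDOW_END
    in_w = licks[(licks >= w0) & (licks < w1)]
    n = int(in_w.size)

    go = False
    seventh = None
    if n >= HIT_LICK_COUNT:
        first7 = in_w[:HIT_LICK_COUNT]
        if np.all(np.diff(first7) <= MAX_INTERLICK_GAP):
            go = True
            seventh = float(first7[-1])

    if go:
        outcome = "hit"
    elif n == 0:
        outcome = "miss"
    else:
        outcome = "partial_hit"

    rtype = "none"
    if go:
        rtype = "reward" if reinforcement_map is None else reinforcement_map.get(tone, "reward")
    return TrialRecord(
        onset_s=float(onset_s),
        tone=tone,
        outcome=outcome,
        go=go,
        lick_count_in_window=n,
        seventh_lick_s=seventh,
        reinforcement_type=rtype,
        phase=phase,
    )


def detect_abort(onset_s: float, licks: np.ndarray, phase: int = 1) -> bool:
    """True iff any lick falls in the pre-stimulus withhold window.

    The window is ``[onset - w, onset)`` with w = 2.0 s (Phase 1) or 1.5 s
    (Phase 2).
    """
    licks = _check_sorted(licks)
    w = WITHHOLD_S[int(phase)]
    return bool(np.any((licks >= onset_s - w) & (licks < onset_s)))


def score_session(
    events: SessionEvents, reinforcement_map: dict[str, str] | None = None
) -> list[TrialRecord]:
    """Score every trial of a session, marking aborted trials.

    Aborted trials (lick during withhold) carry outcome ``"aborted"``,
    ``go=False`` and no reinforcement.
    """
    out = []
    for onset, tone, phase in events.stim_onsets:
        if detect_abort(onset, events.licks, phase):
            rec = TrialRecord(
                onset_s=float(onset),
                tone=tone,
                outcome="aborted",
                go=False,
                lick_count_in_window=0,
                seventh_lick_s=None,
                reinforcement_type="none",
                phase=phase,
            )
        else:
            rec = score_trial(onset, events.licks, phase, tone, reinforcement_map)
        rec.session_id = events.session_id
        rec.mouse_id = events.mouse_id
        out.append(rec)
    return out


def find_intertrial_bouts(
    licks: np.ndarray, trial_windows: list[tuple[float, float]]
) -> list[LickBout]:
    """Detect inter-trial lick bouts.

    A bout is a maximal run of licks outside every trial window whose
    consecutive gaps are strictly below 250 ms, flanked on both sides by at
    least 1 s without any lick (quiescence is judged against ALL licks, so a
    run abutting trial-window licking does not qualify).  Runs of a single
    lick count as size-1 bouts; size bins are 1-2, 3-4, 5-6, 7+.
    """
    licks = _check_sorted(licks)
    if licks.size == 0:
        return []
    in_trial = np.zeros(licks.size, dtype=bool)
    for start, end in trial_windows:
        in_trial |= (licks >= start) & (licks < end)
    free = licks[~in_trial]
    if free.size == 0:
        return []

    bouts: list[LickBout] = []
    run_start = 0
    for i in range(1, free.size + 1):
        if i < free.size and free[i] - free[i - 1] < BOUT_MAX_GAP:
            continue
        run = free[run_start:i]
        run_start = i
        # quiescence against the full lick stream
        before = licks[(licks < run[0]) & (licks > run[0] - BOUT_QUIESCENCE)]
        after = licks[(licks > run[-1]) & (licks < run[-1] + BOUT_QUIESCENCE)]
        if before.size == 0 and after.size == 0:
            bouts.append(
                LickBout(
                    start_s=float(run[0]),
                    end_s=float(run[-1]),
                    n_licks=int(run.size),
                    size_bin=bout_size_bin(int(run.size)),
                )
            )
    return bouts


def go_probability_curve(
    trials: list[TrialRecord], n_bins: int = 5
) -> dict[str, np.ndarray]:
    """Per-tone Go probability across equal-count training-time bins.

    Trials are ordered by onset time and split into ``n_bins`` bins of (near)
    equal trial count.  Within each bin and tone class the Go probability is
    go-trials / non-aborted trials; a tone absent from a bin yields NaN
    (missing, not zero).
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    trials = sorted(trials, key=lambda t: t.onset_s)
    tones = sorted({t.tone for t in trials})
    splits = np.array_split(np.arange(len(trials)), n_bins)
    out = {tone: np.full(n_bins, np.nan) for tone in tones}
    for b, idx in enumerate(splits):
        for tone in tones:
            sub = [trials[i] for i in idx if trials[i].tone == tone and trials[i].outcome != "aborted"]
            if sub:
                out[tone][b] = float(np.mean([t.go for t in sub]))
    return out
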