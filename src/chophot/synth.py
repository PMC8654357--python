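"""Synthetic dual-fiber photometry sessions with known ground truth.

The generator emulates the statistical structure every downstream stage
assumes, so the whole pipeline can be verified without real recordings:

* a slow latent arousal process (Ornstein-Uhlenbeck, time constant ~10 s)
  that drives fluorescence directly and pupil diameter after a configurable
  delay (fluorescence leads pupil, positive ``coupling_lag_s``);
* stimulus/reinforcement-evoked calcium transients built from a
  difference-of-exponentials kernel (50 ms rise, 600 ms decay — GCaMP6f-like)
  with region- and outcome-dependent amplitudes and per-trial multiplicative
  habituation;
* slow mono-exponential bleaching, white measurement noise, and a 405 nm
  channel carrying bleach plus shared motion noise but no calcium term;
* an operant lick agent producing criterion bouts on scheduled hit trials
  (≥7 licks starting 0.2–0.5 s post-onset, gaps well under 1 s), sparse
  inter-trial bouts from a renewal process, and a trial schedule with
  truncated-exponential inter-trial intervals in a 7–10 s range (rewarded
  tone on 50% of Phase-2 trials, the other two outcomes on 25% each).

Amplitudes are specified on the ΔF/F₀ scale (the session z denominator is a
property of each realization, not of the configuration); ground truth is
recorded on the same scale.  Identical configurations (including the seed)
reproduce bit-identical output.

``render_eye_frame`` draws a synthetic eye image (dark elliptical pupil on a
brighter iris, optional eyelid band and specular highlights) as a test
substrate for the pupil segmentation algorithm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal as sps

from .behavior import SessionEvents, WITHHOLD_S
from .traces import FluorescenceTrace, PupilTrace

__all__ = [
    "TrialSchedule",
    "SimConfig",
    "GroundTruth",
    "simulate_session",
    "render_eye_frame",
    "render_eye_stack",
    "transient_kernel",
]

REGIONS = ("HDB", "GP/SI")


@dataclass
class TrialSchedule:
    """Trial timing and outcome schedule.

    Phase 1 presents three tone frequencies with equal probability, all
    rewarded.  Phase 2 keeps one rewarded tone (50% of trials) and maps the
    other two to shock and reward omission (25% each).  Inter-trial
    intervals are drawn from an exponential (scale ``iti_scale_s``)
    truncated to ``iti_range_s``.  ``go_prob`` is the behavioral agent's
    per-tone probability of producing the criterion lick bout.
    """

    phase: int = 1
    tone_probs: dict[str, float] = field(default_factory=dict)
    iti_range_s: tuple[float, float] = (7.0, 10.0)
    iti_scale_s: float = 3.0
    go_prob: dict[str, float] = field(default_factory=dict)
    partial_prob: float = 0.05
    abort_prob: float = 0.02
    first_onset_s: float = 12.0

    def __post_init__(self) -> None:
        if not self.tone_probs:
            if self.phase == 1:
                self.tone_probs = {"low": 1 / 3, "mid": 1 / 3, "high": 1 / 3}
            else:
                self.tone_probs = {"low": 0.5, "mid": 0.25, "high": 0.25}
        total = sum(self.tone_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("tone probabilities must sum to 1")
        if not self.go_prob:
            if self.phase == 1:
                self.go_prob = {t: 0.8 for t in self.tone_probs}
            else:
                self.go_prob = {"low": 0.85, "mid": 0.25, "high": 0.4}

    @property
    def reinforcement_map(self) -> dict[str, str]:
        if self.phase == 1:
            return {t: "reward" for t in self.tone_probs}
        return {"low": "reward", "mid": "shock", "high": "omission"}


@dataclass
class SimConfig:
    """Full parameterization of one synthetic session (see module docstring).

    Rates/durations are in the units of the field names; amplitude-like
    parameters are on the ΔF/F₀ scale.  Spontaneous-transient rate and
    amplitude are free parameters of the emulation (no empirical values are
    available for them) and are exposed here rather than hard-coded.
    """

    seed: int = 0
    duration_s: float = 1200.0
    fs_photometry: float = 1017.0
    fs_pupil: float = 30.0
    # latent arousal
    arousal_tau_s: float = 10.0
    arousal_sd: float = 0.015
    coupling_lag_s: float = 0.7
    pupil_lowpass_hz: float = 1.0
    # transient kernel
    kernel_rise_s: float = 0.05
    kernel_decay_s: float = 0.6
    # event response amplitudes (dF/F0 units), per class and region
    event_amplitudes: dict[str, dict[str, float]] = field(default_factory=dict)
    habituation_rate: float = 0.0
    miss_baseline_elevation: dict[str, float] = field(default_factory=dict)
    # spontaneous transients
    spont_rate_hz: float = 0.08
    spont_amp: dict[str, float] = field(default_factory=dict)
    # measurement model
    f0: dict[str, float] = field(default_factory=lambda: {r: 100.0 for r in REGIONS})
    bleach_tau_s: float = 3600.0
    noise_sd: float = 0.003
    # pupil measurement
    pupil_base_px: float = 40.0
    pupil_gain_px: float = 250.0
    pupil_noise_px: float = 0.15
    # licking
    bout_rate_hz: float = 0.04
    intra_bout_ili_s: tuple[float, float] = (0.09, 0.2)
    trial_schedule: TrialSchedule = field(default_factory=TrialSchedule)

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        for name in ("fs_photometry", "fs_pupil", "arousal_tau_s", "kernel_rise_s",
                     "kernel_decay_s", "bleach_tau_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.coupling_lag_s < 0:
            raise ValueError("coupling_lag_s must be >= 0 (fluorescence leads)")
        if not self.event_amplitudes:
            # qualitative regional ordering: tones & shock stronger caudally
            # (GP/SI), reward omission stronger rostrally (HDB), reward weak
            self.event_amplitudes = {
                "tone": {"HDB": 0.010, "GP/SI": 0.030},
                "reward": {"HDB": 0.004, "GP/SI": 0.004},
                "shock": {"HDB": 0.035, "GP/SI": 0.060},
                "omission": {"HDB": 0.025, "GP/SI": 0.008},
            }
        if not self.spont_amp:
            self.spont_amp = {r: 0.012 for r in REGIONS}


@dataclass
class GroundTruth:
    """Everything the observables were derived from (given the seed)."""

    latent_arousal: np.ndarray
    true_lag_s: float
    trial_table: list[dict]
    true_event_amplitudes: dict[str, np.ndarray]  # per region, per trial (tone)
    true_reinforcement_amplitudes: dict[str, np.ndarray]
    true_transient_times: dict[str, np.ndarray]
    true_pupil_diameter: np.ndarray


def transient_kernel(fs: float, rise_s: float, decay_s: float) -> np.ndarray:
    """Difference-of-exponentials kernel normalized to unit peak."""
    if decay_s <= rise_s:
        raise ValueError("kernel decay must exceed rise")
    t = np.arange(0.0, 8.0 * decay_s, 1.0 / fs)
    k = np.exp(-t / decay_s) - np.exp(-t / rise_s)
    return k / k.max()


def _ou(rng: np.random.Generator, n: int, dt: float, tau: float, sd: float) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck path (exact AR(1) discretization)."""
    if sd == 0:
        return np.zeros(n)
    rho = np.exp(-dt / tau)
    innov = rng.standard_normal(n) * (sd * np.sqrt(1.0 - rho * rho))
    x0 = float(rng.standard_normal() * sd)
    innov[0] = x0 * (1.0 - rho)  # so the filtered series starts exactly at x0
    x, _ = sps.lfilter([1.0], [1.0, -rho], innov, zi=[rho * x0])
    return x


def _truncexp(rng: np.random.Generator, lo: float, hi: float, scale: float) -> float:
    u = rng.random()
    return lo - scale * np.log1p(-u * (1.0 - np.exp(-(hi - lo) / scale)))


def _schedule_trials(cfg: SimConfig, rng: np.random.Generator) -> list[dict]:
    sch = cfg.trial_schedule
    tones = list(sch.tone_probs)
    probs = np.array([sch.tone_probs[t] for t in tones])
    trials = []
    t = sch.first_onset_s
    # leave room for the response window and post-event metric windows
    while t < cfg.duration_s - 12.0:
        tone = tones[rng.choice(len(tones), p=probs)]
        aborted = rng.random() < sch.abort_prob
        go = (not aborted) and (rng.random() < sch.go_prob[tone])
        partial = (not aborted) and (not go) and (rng.random() < sch.partial_prob)
        trials.append(
            {
                "onset_s": float(t),
                "tone": tone,
                "phase": sch.phase,
                "scheduled": "aborted" if aborted else ("hit" if go else ("partial_hit" if partial else "miss")),
                "reinforcement": sch.reinforcement_map[tone] if go else "none",
            }
        )
        t += 3.0 + _truncexp(rng, *sch.iti_range_s, sch.iti_scale_s)
    return trials


def _agent_licks(cfg: SimConfig, trials: list[dict], rng: np.random.Generator) -> np.ndarray:
    """Lick timestamps: trial responses plus inter-trial renewal bouts."""
    sch = cfg.trial_schedule
    licks: list[float] = []
    for tr in trials:
        onset = tr["onset_s"]
        if tr["scheduled"] == "aborted":
            w = WITHHOLD_S[sch.phase]
            licks.append(onset - rng.uniform(0.15, max(w - 0.1, 0.2)))
            continue
        if tr["scheduled"] == "hit":
            t = onset + rng.uniform(0.2, 0.5)
            n_extra = rng.integers(0, 4)
            n_licks = 7 + int(n_extra)
            for j in range(n_licks):
                licks.append(t)
                t += rng.uniform(*cfg.intra_bout_ili_s)
        elif tr["scheduled"] == "partial_hit":
            t = onset + rng.uniform(0.3, 0.8)
            for j in range(int(rng.integers(1, 7))):
                licks.append(t)
                t += rng.uniform(*cfg.intra_bout_ili_s)

    # inter-trial bouts: Poisson bout starts, truncated-geometric sizes
    exclusion = [
        (tr["onset_s"] - WITHHOLD_S[sch.phase] - 1.5, tr["onset_s"] + 6.0)
        for tr in trials
    ]
    n_bouts = rng.poisson(cfg.bout_rate_hz * cfg.duration_s)
    starts = np.sort(rng.uniform(2.0, cfg.duration_s - 4.0, size=n_bouts))
    last_end = -np.inf
    sizes = (1, 2, 3, 4, 5, 6, 7, 8, 9)
    size_p = np.array([0.30, 0.22, 0.13, 0.09, 0.07, 0.05, 0.06, 0.05, 0.03])
    for s in starts:
        if s - last_end < 1.5:
            continue
        if any(a < s < b for a, b in exclusion):
            continue
        n = sizes[rng.choice(len(sizes), p=size_p)]
        t = float(s)
        for _ in range(n):
            licks.append(t)
            t += rng.uniform(*cfg.intra_bout_ili_s)
        last_end = t
    return np.sort(np.asarray(licks))


def _seventh_lick(onset: float, licks: np.ndarray) -> float | None:
    in_w = licks[(licks >= onset + 0.2) & (licks < onset + 3.0)]
    return float(in_w[6]) if in_w.size >= 7 else None


def simulate_session(
    config: SimConfig,
) -> tuple[dict[str, FluorescenceTrace], PupilTrace, SessionEvents, GroundTruth]:
    """Generate one complete synthetic session.

    Returns per-region fluorescence traces (465 + 405 channels), the true
    pupil trace sampled at the camera rate, the behavioral event streams,
    and the ground truth all observables derive from.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.fs_photometry
    n = int(round(cfg.duration_s * fs))
    t = np.arange(n) / fs
    dt = 1.0 / fs

    arousal = _ou(rng, n, dt, cfg.arousal_tau_s, cfg.arousal_sd)
    trials = _schedule_trials(cfg, rng)
    licks = _agent_licks(cfg, trials, rng)
    kernel = transient_kernel(fs, cfg.kernel_rise_s, cfg.kernel_decay_s)

    events_re: list[tuple[float, str]] = []
    calcium: dict[str, np.ndarray] = {r: np.zeros(n) for r in REGIONS}
    tone_amps: dict[str, list[float]] = {r: [] for r in REGIONS}
    reinf_amps: dict[str, list[float]] = {r: [] for r in REGIONS}
    spont_times: dict[str, np.ndarray] = {}

    def _add(region: str, time_s: float, amp: float) -> None:
        i0 = int(round(time_s * fs))
        if i0 >= n or amp == 0:
            return
        seg = kernel[: n - i0]
        calcium[region][i0 : i0 + seg.size] += amp * seg

    n_presented = 0
    for tr in trials:
        onset = tr["onset_s"]
        decay = (1.0 - cfg.habituation_rate) ** n_presented
        if tr["scheduled"] != "aborted":
            n_presented += 1
        for r in REGIONS:
            a = cfg.event_amplitudes.get("tone", {}).get(r, 0.0) * decay
            if tr["scheduled"] == "aborted":
                a = 0.0
            tone_amps[r].append(a)
            _add(r, onset, a)
        seventh = _seventh_lick(onset, licks) if tr["scheduled"] == "hit" else None
        tr["seventh_lick_s"] = seventh
        if seventh is not None:
            rtype = tr["reinforcement"]
            events_re.append((seventh, rtype))
            # omission responses develop later than reward/shock responses
            delay = 0.4 if rtype == "omission" else 0.0
            for r in REGIONS:
                a = cfg.event_amplitudes.get(rtype, {}).get(r, 0.0)
                reinf_amps[r].append(a)
                _add(r, seventh + delay, a)
        else:
            for r in REGIONS:
                reinf_amps[r].append(0.0)
        # pre-cue state elevation on scheduled miss trials (per region)
        if tr["scheduled"] == "miss" and cfg.miss_baseline_elevation:
            i0 = int(round((onset - 2.0) * fs))
            i1 = int(round((onset + 0.5) * fs))
            if 0 <= i0 < i1 <= n:
                bump = np.hanning(i1 - i0)
                for r, amp in cfg.miss_baseline_elevation.items():
                    calcium[r][i0:i1] += amp * bump

    for r in REGIONS:
        n_sp = rng.poisson(cfg.spont_rate_hz * cfg.duration_s)
        times = np.sort(rng.uniform(0.0, cfg.duration_s - 1.0, size=n_sp))
        spont_times[r] = times
        amp0 = cfg.spont_amp.get(r, 0.0)
        for ts in times:
            _add(r, float(ts), amp0 * np.exp(rng.normal(0.0, 0.3)))

    bleach = np.exp(-t / cfg.bleach_tau_s)
    fluo: dict[str, FluorescenceTrace] = {}
    for r in REGIONS:
        motion = 0.5 * cfg.noise_sd * rng.standard_normal(n) if cfg.noise_sd else 0.0
        noise465 = cfg.noise_sd * rng.standard_normal(n) if cfg.noise_sd else 0.0
        f465 = cfg.f0[r] * bleach * (1.0 + arousal + calcium[r] + motion + noise465)
        f405 = 0.7 * cfg.f0[r] * bleach * (1.0 + motion)
        fluo[r] = FluorescenceTrace(
            fs=fs, values_465=f465, values_405=f405, fiber_id=r
        )

    # pupil: latent arousal delayed by the coupling lag, low-passed (zero
    # phase, so the filter adds no extra lag), mapped affinely to pixels
    shift = int(round(cfg.coupling_lag_s * fs))
    delayed = np.concatenate([np.full(shift, arousal[0]), arousal[: n - shift]]) if shift else arousal
    if cfg.pupil_lowpass_hz < fs / 2 and cfg.arousal_sd > 0:
        b, a = sps.butter(2, cfg.pupil_lowpass_hz, btype="low", fs=fs)
        smooth = sps.filtfilt(b, a, delayed, padtype="even",
                              padlen=min(n - 1, int(3 * fs / cfg.pupil_lowpass_hz)))
    else:
        smooth = delayed
    n_frames = int(np.floor(cfg.duration_s * cfg.fs_pupil))
    t_frames = np.arange(n_frames) / cfg.fs_pupil
    diam = cfg.pupil_base_px + cfg.pupil_gain_px * np.interp(t_frames, t, smooth)
    if cfg.pupil_noise_px:
        diam = diam + cfg.pupil_noise_px * rng.standard_normal(n_frames)
    pupil = PupilTrace(fs=cfg.fs_pupil, diameter=diam)

    events = SessionEvents(
        stim_onsets=[(tr["onset_s"], tr["tone"], tr["phase"]) for tr in trials],
        licks=licks,
        reinforcement=sorted(events_re),
        session_id=f"sim-{cfg.seed}",
        mouse_id="simulated",
    )
    truth = GroundTruth(
        latent_arousal=arousal,
        true_lag_s=cfg.coupling_lag_s,
        trial_table=trials,
        true_event_amplitudes={r: np.asarray(v) for r, v in tone_amps.items()},
        true_reinforcement_amplitudes={r: np.asarray(v) for r, v in reinf_amps.items()},
        true_transient_times=spont_times,
        true_pupil_diameter=diam.copy(),
    )
    return fluo, pupil, events, truth


# ---------------------------------------------------------------------------
# synthetic eye frames


def render_eye_frame(
    diameter_px: float,
    center: tuple[float, float],
    eccentricity: float = 1.0,
    occlusion_frac: float = 0.0,
    highlight_spec: list[tuple[float, float, float]] | None = None,
    seed: int = 0,
    frame_shape: tuple[int, int] = (120, 160),
    angle_deg: float = 0.0,
) -> tuple[np.ndarray, float]:
    """Render a synthetic eye frame; returns (uint8 image, true diameter).

    The pupil is a dark ellipse of area-equivalent diameter ``diameter_px``
    (semi-axes ``r·√e`` and ``r/√e`` for axis ratio ``e``) on a brighter
    iris disk on a bright scleral field.  ``occlusion_frac`` draws a bright
    eyelid band over the top fraction of the pupil's vertical extent;
    ``highlight_spec`` entries ``(dx_frac, dy_frac, r_frac)`` place bright
    specular blobs at offsets/radii in units of the pupil diameter.
    Rendering is 4× supersampled, lightly blurred and noised.

    The returned ground-truth diameter is that of the full (unoccluded)
    ellipse.
    """
    if diameter_px <= 0:
        raise ValueError("diameter_px must be positive")
    if not 0 <= occlusion_frac < 0.5:
        raise ValueError("occlusion_frac must lie in [0, 0.5)")
    if not 1.0 <= eccentricity <= 2.0:
        raise ValueError("eccentricity (axis ratio) must lie in [1, 2]")
    h, w = frame_shape
    cx, cy = center
    r = diameter_px / 2.0
    a = r * np.sqrt(eccentricity)  # semi-major
    b = r / np.sqrt(eccentricity)  # semi-minor
    ext = max(a, b)
    if cx - ext < 1 or cx + ext > w - 1 or cy - ext < 1 or cy + ext > h - 1:
        raise ValueError("pupil extends beyond the frame")

    ss = 4
    yy, xx = np.mgrid[0 : h * ss, 0 : w * ss]
    xs = (xx + 0.5) / ss
    ys = (yy + 0.5) / ss
    img = np.full((h * ss, w * ss), 215.0)

    iris_r = max(1.15 * diameter_px, ext + 10.0)
    img[(xs - cx) ** 2 + (ys - cy) ** 2 <= iris_r**2] = 135.0

    th = np.deg2rad(angle_deg)
    u = (xs - cx) * np.cos(th) + (ys - cy) * np.sin(th)
    v = -(xs - cx) * np.sin(th) + (ys - cy) * np.cos(th)
    pupil = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    img[pupil] = 30.0

    for dxf, dyf, rf in highlight_spec or ():
        hx = cx + dxf * diameter_px
        hy = cy + dyf * diameter_px
        hr = rf * diameter_px
        img[(xs - hx) ** 2 + (ys - hy) ** 2 <= hr**2] = 250.0

    if occlusion_frac > 0:
        # eyelid: bright skin with a dark shadowed margin (lash line), as in
        # infrared eye video -- the margin over the pupil is low-contrast
        y_top = cy - b
        y_band = y_top + occlusion_frac * 2.0 * b
        lid = ys <= y_band
        ramp = np.clip((y_band - ys) / 4.0, 0.0, 1.0)
        img[lid] = (100.0 + 90.0 * ramp)[lid]

    img = img.reshape(h, ss, w, ss).mean(axis=(1, 3))
    img = ndimage.gaussian_filter(img, 0.5)
    rng = np.random.default_rng(seed)
    img = img + rng.normal(0.0, 1.0, size=img.shape)
    return np.clip(img, 0, 255).astype(np.uint8), float(diameter_px)


def render_eye_stack(
    diameters_px: np.ndarray,
    frame_shape: tuple[int, int] = (120, 160),
    seed: int = 0,
) -> np.ndarray:
    """Render a stack of centered circular-pupil frames for given diameters."""
    h, w = frame_shape
    frames = []
    for i, d in enumerate(np.asarray(diameters_px, dtype=float)):
        img, _ = render_eye_frame(
            d, (w / 2, h / 2), seed=seed + i, frame_shape=frame_shape
        )
        frames.append(img)
    return np.stack(frames)
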