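# Methods

This note documents the models, parameter choices and numerical decisions
behind each stage of the pipeline, what the synthetic-session generator
does and does not emulate, and the known limitations.

## Photometry preprocessing

The raw demodulated 465 nm signal is converted to ΔF/F₀ with a running
median baseline (60 s window).  The window is **centered** by default and
**truncates** (shrinks) at trace edges rather than padding — no data are
invented at the ends, and the brute-force oracle used in the tests
implements exactly the same convention.  A trailing window is available
(`mode="trailing"`) for causal applications; whether the original analyses
centered or trailed their window is not documented, and the two differ only
in a group delay of half a window.  At the nominal 1017 Hz rate the
centered 60 s window spans 61,021 samples; the implementation uses the
pandas skip-list rolling median (O(n log w)), which handles a 20-minute
session in ≈1.5 s.

"Zero-lag" filtering is realized as forward–backward application of a
second-order Butterworth low-pass (7 Hz default), giving a symmetric
impulse response and a squared single-pass magnitude response — a sinusoid
at the corner frequency emerges at exactly half its input amplitude, which
the tests assert.  Edge transients are controlled with reflective padding
of at least `3·fs/cutoff` samples.  Interior samples commute with time
reversal to ~1e-13; the outermost samples carry ~1e-6 of residual
edge-padding asymmetry.

Z-scoring pools all samples from the supplied baseline windows (2 s
pre-stimulus in passive sessions; 2 s pre-cue pooled across trials in
operant sessions) and stores (μ, σ) so the transform is exactly invertible.
A baseline whose standard deviation is at floating-point noise level is
rejected as degenerate.

The 405 nm channel is carried through I/O as a QC signal only; no
isosbestic regression or motion correction is applied anywhere in the
chain.

**Order of steps** is fixed: ΔF/F₀ → low-pass → z-score.

## Pupil segmentation

The frame-wise algorithm: binarize (pupil pixels below threshold, largest
connected component), center of mass, initial circle with area equal to
the pupil pixel count, Canny edges, then two filters — edge pixels must lie
within 3 px of a pupil pixel **and** inside the annulus whose inner/outer
diameters are 0.5× and 1.75× the initial circle's diameter (read as bounds
on radial distance from the circle's **center**; the alternative
boundary-distance reading is not used) — and finally an ellipse fit, with
the area-equivalent diameter 2√(ab) reported.  Frames with fewer than five
surviving edge pixels or a non-elliptical conic are flagged invalid rather
than raising.

Several defaults extend the basic chain; each is an explicit
`SegmentationParams` field and can be switched off:

- **Threshold selection** (`intensity_threshold=None`): recursive Otsu.
  Eye frames are multi-modal (pupil, iris, eyelid, sclera) and the pupil is
  often a small minority of pixels, so a single Otsu split lands between
  the bright modes.  The threshold walks down through recursive splits of
  the dark population and the first (deepest) candidate whose largest dark
  component is *pupil-like* — at least 25 px and filling ≥ 45 % of the disk
  spanned by its bounding box — wins.  The compactness test rejects eyelid
  streaks and noise speckle.  A fixed threshold and an eye ROI are
  supported for recorded video.
- **Edge scale** `canny_sigma = 0.7`: localization accuracy for small
  pupils; heavier smoothing drags the detected boundary of strongly curved
  edges inward.
- **Subpixel refinement** (`subpixel=True`): each integer Canny pixel is
  moved along its gradient direction to the parabolic peak of the gradient
  magnitude, removing most half-pixel quantization error.
- **Curvature correction** (`curvature_correction=True`): Gaussian edge
  smoothing at scale σ shifts the gradient peak of a boundary with local
  radius r inward to r − σ²/r; the fitted semi-axes are corrected by
  inverting that relation with σ = `canny_sigma`.
- **Robust consensus** (`robust=True`): before the final least-squares fit,
  a seeded RANSAC (residual 0.35 px, ≤ 100 trials) keeps the largest
  edge-pixel subset consistent with a single ellipse.  This is what makes
  the fit survive structured non-boundary contours — the chord a partially
  closed eyelid draws across the pupil, or the rim of a specular highlight
  that reaches past the inner annulus.  Without it, a 20 % eyelid band
  biases the recovered diameter ≈ 6 % low.

With these defaults, recovery on rendered frames (diameters 10–60 px) is
≲ 0.7 % worst-case for clean/specular frames and ≲ 3 % under a 20 % eyelid
band.  The annulus filter rejects interior specular rims by design only
when the highlight stays within half the pupil diameter of the center —
the geometry of coaxial infrared illumination; rim-touching highlights
defeat any edge-based fit.

The landmark variant filters eight compass points by confidence (cutoff
0.9), requires ≥ 5 survivors for the conic, and reports the **long-axis**
diameter — deliberately different from the area-equivalent convention, and
always ≥ it, with equality only for circles.

Gap repair (`preprocess_pupil_trace`) linearly interpolates invalid frames
and holds end gaps at the nearest valid value; traces more than 50 %
invalid are rejected rather than repaired.

## Fluorescence–pupil coupling

Photometry is brought to the pupil clock (30 Hz) by a zero-phase Kaiser
FIR low-pass (passband to 0.65× the common Nyquist, ≥ 65 dB stopband from
0.9× Nyquist; doubled by the forward–backward pass) followed by linear
interpolation at frame times.  Coherence uses Welch averaging with a
Hamming taper, 1500-sample windows, 1400-sample overlap and FFT length
equal to the window (no zero padding).  Both series are linearly detrended
by default (`detrend_linear=False` disables it); scipy additionally removes
per-segment means.  The lag estimator computes the Pearson correlation of
the overlapping segments at every integer lag within ±5 s and returns the
argmax; ties resolve to the smallest |lag| (then the positive one) and are
flagged.  The estimator is exactly antisymmetric under argument exchange.

## Behavior

Scoring constants follow the task definition: response window
[onset + 0.2 s, onset + 3.0 s), half-open; hit requires ≥ 7 licks in the
window with every gap among the first seven ≤ 1 s (licks after the seventh
are ignored); reinforcement — and the virtual omission event — is timed to
the seventh lick.  The withhold window is [onset − 2 s, onset) in Phase 1
and 1.5 s in Phase 2; any lick there aborts the trial, and aborted trials
carry no outcome score.  Bout detection uses strict < 250 ms gaps and
inclusive ≥ 1 s quiescence, with quiescence judged against **all** licks so
a run abutting trial-window licking does not qualify.  Although the formal
bout definition requires two contacts, single licks flanked by quiescence
are counted as size-1 bouts so that the 1–2 bin of the bout-size analysis
is populated — lone spout checks are real behavior.

Go probability curves split trials (ordered by onset) into equal-count
bins; the denominator is non-aborted trials and the numerator is trials
meeting the go criterion, regardless of reinforcement.  An empty tone×bin
cell is NaN (missing), never zero.  Session-level training-time bins use
bin = ⌈n_bins · fraction-completed⌉, so 8 sessions into 5 bins gives sizes
(1, 2, 1, 2, 2).

## Event metrics

Each figure-level metric is a named config (alignment event, baseline
window + statistic, response window + statistic).  Two amplitude
conventions coexist deliberately: the passive sensory metric subtracts the
baseline mean from both a response-window peak and a 0.4 s pre-onset peak
and reports post − pre, while the operant tone and reinforcement metrics
subtract only the baseline statistic.  "Peak" is the maximum (responses of
interest are positive-going) and peak latency takes the earliest maximum
on ties.  Events whose windows cross a trace edge are skipped, never
zero-padded.  The spontaneous-transient statistic applies its +0.5 offset
on the session z-score scale established by baseline z-scoring; its
threshold is the linear-interpolation 5th percentile, matching the
sort-and-scan oracle in the tests.  The 7-point median filter is a display
smoother only and is excluded from slope fits.

## Decoding

Features are mean ΔF/F₀ in consecutive 10 ms bins (100 bins for the 1 s
pre-cue window, 40 for the 400 ms post-cue window, concatenated across the
selected fibers).  Each of 50 iterations downsamples the majority class to
balance the design, then runs leave-one-out cross-validation; PCA (components
to 90 % variance) is fitted **inside each training fold** to avoid
test-row leakage — a whole-matrix mode (`pca_per_fold=False`) exists for
comparison with analyses that reduce once per session.  The SVM is linear
with the conventional regularization C = 1; features are centered by PCA
but not variance-scaled, since all share z units.  Since leave-one-out is
deterministic, iterations differ only in the downsampling draw (and the
label permutation in the randomized control).  Note that balanced LOO is
slightly conservative under the null: holding out one sample leaves the
training set imbalanced against the held-out class, so label-randomized
accuracy sits a few points below 0.5 (~0.46 in our tests) rather than at
it.

## Synthetic sessions

The generator produces everything downstream stages consume, from a single
seed, bit-reproducibly:

- **Latent arousal**: stationary Ornstein–Uhlenbeck process (τ = 10 s,
  sd = 0.015 ΔF/F units).  With τ = 10 s, > 80 % of its power lies below
  0.1 Hz.  Fluorescence carries the arousal directly; pupil carries it
  delayed by `coupling_lag_s` (default 0.7 s, fluorescence leading),
  low-passed at 1 Hz with a zero-phase filter (so the smoothing adds no
  extra lag), mapped affinely to pixels (40 px baseline, 250 px per unit),
  plus 0.15 px frame noise.
- **Transients**: difference-of-exponentials kernel, 50 ms rise / 600 ms
  decay (GCaMP6f-like), unit peak.  Event amplitudes are configured per
  class and region **on the ΔF/F₀ scale** (the z denominator is a property
  of each realization, so z units cannot be promised a priori); defaults
  encode the qualitative regional ordering — tone and shock responses
  stronger caudally (GP/SI), reward-omission stronger rostrally (HDB),
  anticipated reward weak in both — with per-trial multiplicative
  habituation available.  Omission responses are injected 0.4 s later than
  reward/shock, echoing their slower build.  Spontaneous transient rate
  (0.08 Hz) and amplitude (0.012) are free parameters of the emulation;
  no empirical values exist for them and they are exposed in `SimConfig`.
- **Measurement model**: F = F₀ · exp(−t/τ_bleach) · (1 + arousal +
  transients + motion + noise) with τ_bleach = 1 h, white noise
  0.003 F₀, and a shared motion term (half the noise amplitude) that is
  the only non-bleach content of the 405 nm channel.  With all variance
  sources off, the 465 nm trace is exactly the bleaching curve.
- **Behavior**: trial onsets separated by 3 s plus a truncated-exponential
  ITI in [7, 10] s (scale 3 s); Phase 1 presents three tones with equal
  probability (all rewarded), Phase 2 presents the rewarded tone on 50 %
  of trials and the shock/omission tones on 25 % each.  The lick agent
  produces criterion bouts (start 0.2–0.5 s post-onset, inter-lick
  intervals 90–200 ms) on scheduled hit trials with per-tone Go
  probabilities (Phase 2 defaults: 0.85 reward, 0.4 neutral, 0.25 shock),
  occasional partial hits and aborts, and sparse inter-trial bouts from a
  renewal process kept clear of trial windows.
- **Eye frames**: dark pupil ellipse (area-equivalent diameter given,
  axis ratio ∈ [1, 2]) on an iris disk on a bright field, 4× supersampled
  with light blur and noise; optional specular blobs and an eyelid band
  whose margin carries a 4 px shadow ramp, as lid margins appear in
  infrared video — the ground truth returned is always the full-ellipse
  diameter.

What the generator does **not** emulate: hemodynamic or movement
artifacts, blinks, video compression, non-stationary lick vigor, learning
dynamics within a session, and any coupling between arousal and behavioral
performance beyond what is explicitly configured (e.g.
`miss_baseline_elevation`).  Passing tests therefore demonstrate
correctness of the computations under the stated statistical structure,
not robustness to every artifact of real recordings.

## Statistics and pipeline

Summaries are mean ± SEM (sd/√n, ddof = 1) with single-observation groups
flagged; aggregation is mouse-level first.  Holm–Bonferroni is implemented
from the step-down formula (sort ascending, multiply by m − i + 1, running
maximum, cap at 1).  Omnibus tests (repeated-measures ANOVA, paired
t-tests) are left to established statistical packages.

The pipeline runner executes preprocess → pupil → coupling → behavior →
metrics → decoding → summary, writes all artifacts plus a manifest
(parameters, stages completed, seed) and a timestamped log, skips the
pupil/coupling stages gracefully when no pupil input exists, and reruns to
byte-identical metric outputs for identical configurations.

## Problem sizes used in the test suite

Lag recovery uses five seeds per configured lag at 20-minute sessions;
pupil recovery uses 200 mixed frames plus 40 occluded frames; the behavior
oracles run 1000 random lick trains each; decoder checks use 40-trial
sessions with 20 iterations (effect ordering, 10 seeds) or 200 iterations
(permutation null); the end-to-end determinism check reruns a 10-minute
session.  These sizes give stable statistics for every assertion while
keeping the default test run in a few minutes.
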