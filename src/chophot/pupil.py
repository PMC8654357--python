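"""Pupil diameter extraction from eye video frames.

Two estimators are provided:

``segment_pupil_frame``
    The threshold / center-of-mass / Canny / annulus / ellipse algorithm.
    The frame is binarized so pupil pixels fall below an intensity
    threshold; an initial circle is placed at the pupil center of mass with
    area equal to the pupil pixel count; Canny edge pixels are kept only if
    they lie within ``proximity_px`` of a pupil pixel AND inside an annulus
    whose inner/outer diameters are 0.5× and 1.75× the initial circle's
    diameter; a direct least-squares ellipse is fit to the survivors and the
    diameter reported is that of the circle with matching area
    (area-equivalent diameter, 2·√(ab)).

``fit_pupil_from_landmarks``
    The landmark variant: eight compass points around the pupil rim with
    per-point confidences; points below the confidence cutoff are dropped,
    an ellipse is fit to the rest and the LONG-AXIS diameter is reported
    (note the deliberate difference from the area-equivalent convention).

The annulus bounds are interpreted as limits on the radial distance of an
edge pixel from the initial circle's center (the alternative reading —
distance from the circle boundary — is not used).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.feature import canny
from skimage.filters import threshold_otsu
from skimage.measure import EllipseModel, label, ransac

from .traces import PupilTrace

__all__ = [
    "SegmentationParams",
    "segment_pupil_frame",
    "segment_stack",
    "fit_pupil_from_landmarks",
    "preprocess_pupil_trace",
    "area_equivalent_diameter",
]


@dataclass
class SegmentationParams:
    """Tunables for :func:`segment_pupil_frame`.

    ``intensity_threshold=None`` selects Otsu's threshold computed on the
    frame restricted to ``roi`` (x, y, w, h), or the whole frame if no ROI is
    given.  ``canny_sigma`` is the Gaussian scale of the edge detector; the default
    is kept below one pixel so that edge localization stays accurate for
    pupils down to ~10 px diameter (heavier smoothing pulls the detected
    boundary of small, strongly curved pupils inward).
    """

    intensity_threshold: float | None = None
    roi: tuple[int, int, int, int] | None = None
    canny_sigma: float = 0.7
    canny_low: float | None = None
    canny_high: float | None = None
    proximity_px: float = 3.0
    annulus_inner_frac: float = 0.5
    annulus_outer_frac: float = 1.75
    min_edge_pixels: int = 5
    subpixel: bool = True
    curvature_correction: bool = True
    robust: bool = True
    ransac_residual_px: float = 0.35
    ransac_max_trials: int = 100

    def __post_init__(self) -> None:
        if not (0 < self.annulus_inner_frac < 1 < self.annulus_outer_frac):
            raise ValueError("annulus fractions must satisfy 0 < inner < 1 < outer")
        if self.proximity_px < 1:
            raise ValueError("proximity_px must be >= 1")


def area_equivalent_diameter(a: float, b: float) -> float:
    """Diameter of the circle whose area matches an ellipse with semi-axes a, b."""
    return 2.0 * float(np.sqrt(a * b))


def _candidate_thresholds(region: np.ndarray, depth: int = 3) -> list[float]:
    """Recursive Otsu splits of the dark population, brightest first.

    Eye frames are multi-modal (pupil, iris, eyelid, sclera) and the pupil
    is often a small fraction of the pixels, so a single Otsu split lands
    between the bright modes; re-splitting the dark side walks the
    threshold down toward the pupil/iris boundary.
    """
    cands: list[float] = []
    cur = region
    for _ in range(depth):
        if cur.size < 50 or np.unique(cur).size < 2:
            break
        t = float(threshold_otsu(cur))
        cands.append(t)
        cur = cur[cur < t]
    return cands


def _largest_component(mask: np.ndarray) -> np.ndarray:
    lab, n = label(mask, return_num=True)
    if n > 1:
        sizes = np.bincount(lab.ravel())
        sizes[0] = 0
        mask = lab == int(np.argmax(sizes))
    return mask


def _pupil_like(component: np.ndarray, min_area: int = 25) -> bool:
    """A pupil candidate is a compact dark blob: its area fills a reasonable
    fraction of the disk spanned by its own bounding box (unlike eyelid
    streaks or noise speckle)."""
    area = int(component.sum())
    if area < min_area:
        return False
    ys, xs = np.nonzero(component)
    extent = max(ys.max() - ys.min() + 1, xs.max() - xs.min() + 1)
    return area / (np.pi / 4.0 * extent**2) >= 0.45


def _pupil_mask(frame: np.ndarray, params: SegmentationParams) -> tuple[np.ndarray, float]:
    if params.intensity_threshold is not None:
        thr = float(params.intensity_threshold)
        mask = frame < thr
        if not mask.any():
            raise ValueError("no sub-threshold pixels: empty pupil")
        return _largest_component(mask), thr

    region = frame
    if params.roi is not None:
        x, y, w, h = params.roi
        region = frame[y : y + h, x : x + w]
    cands = _candidate_thresholds(np.asarray(region, dtype=float))
    if not cands:
        raise ValueError("no sub-threshold pixels: empty pupil")
    # deepest split first: the first threshold whose largest dark component
    # looks like a pupil wins; fall back to the plain Otsu split otherwise
    for thr in reversed(cands):
        mask = _largest_component(frame < thr)
        if mask.any() and _pupil_like(mask):
            return mask, thr
    thr = cands[0]
    mask = frame < thr
    if not mask.any():
        raise ValueError("no sub-threshold pixels: empty pupil")
    return _largest_component(mask), thr


def _filter_edge_pixels(
    edge_yx: np.ndarray,
    pupil_mask: np.ndarray,
    center_yx: tuple[float, float],
    init_diameter: float,
    params: SegmentationParams,
) -> np.ndarray:
    """Apply the proximity and annulus filters to Canny edge pixels.

    ``edge_yx`` is an (N, 2) array of (row, col) coordinates.  A pixel
    survives if its distance to the nearest pupil pixel is at most
    ``proximity_px`` and its radial distance from the initial circle center
    lies in ``[inner_frac, outer_frac] · D/2``.
    """
    if edge_yx.size == 0:
        return edge_yx
    dist_to_pupil = ndimage.distance_transform_edt(~pupil_mask)
    near = dist_to_pupil[edge_yx[:, 0], edge_yx[:, 1]] <= params.proximity_px
    dy = edge_yx[:, 0] - center_yx[0]
    dx = edge_yx[:, 1] - center_yx[1]
    r = np.hypot(dy, dx)
    r_lo = params.annulus_inner_frac * init_diameter / 2.0
    r_hi = params.annulus_outer_frac * init_diameter / 2.0
    return edge_yx[near & (r >= r_lo) & (r <= r_hi)]


def _subpixel_edges(
    frame: np.ndarray, edge_yx: np.ndarray, sigma: float
) -> np.ndarray:
    """Refine integer edge pixels to subpixel positions.

    For each edge pixel the gradient magnitude is sampled one pixel to
    either side along the local gradient direction and a parabola through
    the three values locates the true maximum; the pixel is moved by that
    offset.  This removes most of the half-pixel quantization error of the
    raw edge map, which matters for small pupils where the least-squares
    fit needs sub-pixel boundary accuracy.
    """
    gy = ndimage.gaussian_filter(frame, sigma, order=(1, 0))
    gx = ndimage.gaussian_filter(frame, sigma, order=(0, 1))
    mag = np.hypot(gx, gy)
    y = edge_yx[:, 0].astype(float)
    x = edge_yx[:, 1].astype(float)
    g = np.stack([gy[edge_yx[:, 0], edge_yx[:, 1]], gx[edge_yx[:, 0], edge_yx[:, 1]]])
    norm = np.hypot(g[0], g[1])
    norm[norm == 0] = 1.0
    uy, ux = g[0] / norm, g[1] / norm

    def _sample(yy, xx):
        return ndimage.map_coordinates(mag, [yy, xx], order=1, mode="nearest")

    m0 = mag[edge_yx[:, 0], edge_yx[:, 1]]
    m_minus = _sample(y - uy, x - ux)
    m_plus = _sample(y + uy, x + ux)
    denom = m_minus - 2.0 * m0 + m_plus
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = 0.5 * (m_minus - m_plus) / denom
    delta = np.where(np.isfinite(delta), np.clip(delta, -1.0, 1.0), 0.0)
    return np.column_stack([y + delta * uy, x + delta * ux])


def _fit_ellipse(xy: np.ndarray) -> tuple[float, float, float, float, float] | None:
    """Direct least-squares ellipse fit; None if degenerate/non-elliptical."""
    with np.errstate(all="ignore"):
        model = EllipseModel.from_estimate(xy.astype(float))
    if not model:
        return None
    xc, yc = (float(v) for v in model.center)
    a, b = (float(v) for v in model.axis_lengths)  # semi-axes
    if not (np.isfinite(a) and np.isfinite(b)) or a <= 0 or b <= 0:
        return None
    return xc, yc, a, b, float(model.theta)


def segment_pupil_frame(
    frame: np.ndarray, params: SegmentationParams | None = None
) -> tuple[tuple[float, float, float, float, float] | None, float, bool]:
    """Segment one grayscale frame.

    Returns ``(ellipse, diameter_px, valid)`` where ellipse is
    ``(xc, yc, a, b, theta)`` in pixel coordinates (x = column, y = row) and
    ``diameter_px`` is area-equivalent.  ``valid`` is False when fewer than
    ``min_edge_pixels`` edge pixels survive filtering or the conic fit is not
    an ellipse; an invalid frame reports diameter NaN rather than raising.

    Raises
    ------
    ValueError
        If the frame is empty or contains no sub-threshold pixel.
    """
    if params is None:
        params = SegmentationParams()
    frame = np.asarray(frame, dtype=float)
    if frame.size == 0:
        raise ValueError("empty frame")

    mask, _ = _pupil_mask(frame, params)
    cy, cx = ndimage.center_of_mass(mask)
    area = float(mask.sum())
    init_d = 2.0 * np.sqrt(area / np.pi)

    fmax = frame.max()
    norm = frame / fmax if fmax > 0 else frame
    edges = canny(
        norm,
        sigma=params.canny_sigma,
        low_threshold=params.canny_low,
        high_threshold=params.canny_high,
    )
    edge_yx = np.argwhere(edges)
    kept = _filter_edge_pixels(edge_yx, mask, (cy, cx), init_d, params)
    if kept.shape[0] < params.min_edge_pixels:
        return None, float("nan"), False

    if params.subpixel:
        kept = _subpixel_edges(norm, kept, params.canny_sigma)
    xy = kept[:, ::-1]  # (x, y) order for the conic fit
    if params.robust and xy.shape[0] > params.min_edge_pixels:
        # consensus step before the final least-squares fit: edge pixels that
        # survive the proximity/annulus filters can still include structured
        # non-boundary contours (eyelid chords, specular rims); keep the
        # largest set consistent with a single ellipse
        with np.errstate(all="ignore"):
            model, inliers = ransac(
                xy,
                EllipseModel,
                min_samples=5,
                residual_threshold=params.ransac_residual_px,
                max_trials=params.ransac_max_trials,
                stop_probability=0.9999,
                rng=0,
            )
        if model is not None and inliers is not None and inliers.sum() >= params.min_edge_pixels:
            xy = xy[inliers]
    ellipse = _fit_ellipse(xy)
    if ellipse is None:
        return None, float("nan"), False
    xc, yc, a, b, theta = ellipse
    if params.curvature_correction:
        # Gaussian edge smoothing (scale sigma) pulls the gradient peak of a
        # curved boundary inward to r - sigma^2/r; invert that per axis
        s2 = params.canny_sigma**2
        a = (a + np.sqrt(a * a + 4 * s2)) / 2.0
        b = (b + np.sqrt(b * b + 4 * s2)) / 2.0
        ellipse = (xc, yc, a, b, theta)
    return ellipse, area_equivalent_diameter(a, b), True


def segment_stack(
    frames: np.ndarray, params: SegmentationParams | None = None, fs: float = 30.0
) -> PupilTrace:
    """Run :func:`segment_pupil_frame` over a (n_frames, h, w) stack."""
    n = frames.shape[0]
    diam = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    ellipses = np.full((n, 5), np.nan)
    for i in range(n):
        try:
            ell, d, ok = segment_pupil_frame(frames[i], params)
        except ValueError:
            ell, d, ok = None, float("nan"), False
        diam[i], valid[i] = d, ok
        if ell is not None:
            ellipses[i] = ell
    return PupilTrace(fs=fs, diameter=diam, valid=valid, ellipse_params=ellipses)


def fit_pupil_from_landmarks(
    points: np.ndarray,
    confidences: np.ndarray,
    p_cutoff: float = 0.9,
) -> tuple[tuple[float, float, float, float, float] | None, float, bool]:
    """Ellipse fit to tracked pupil-rim landmarks.

    Eight compass points (four cardinal, four intercardinal) with per-point
    confidences.  Points with confidence below ``p_cutoff`` are discarded;
    at least five must remain to determine the conic.  Reported diameter is
    the LONG-AXIS length, ``2·max(a, b)``.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    confidences = np.asarray(confidences, dtype=float)
    if confidences.shape[0] != points.shape[0]:
        raise ValueError("points and confidences must have equal length")
    keep = points[confidences >= p_cutoff]
    if keep.shape[0] < 5:
        return None, float("nan"), False
    ellipse = _fit_ellipse(keep)
    if ellipse is None:
        return None, float("nan"), False
    _, _, a, b, _ = ellipse
    return ellipse, 2.0 * max(a, b), True


def preprocess_pupil_trace(trace: PupilTrace, max_invalid_frac: float = 0.5) -> PupilTrace:
    """Fill invalid frames by linear interpolation between valid neighbors.

    Leading/trailing invalid frames are held at the nearest valid value.
    The output keeps the original validity flags (marking which frames were
    interpolated); ``fraction_invalid`` reports the repair rate.

    Raises
    ------
    ValueError
        If more than ``max_invalid_frac`` of frames are invalid — such a
        trace is rejected rather than repaired.
    """
    frac_bad = trace.fraction_invalid
    if frac_bad > max_invalid_frac:
        raise ValueError(
            f"{frac_bad:.0%} of frames invalid exceeds the "
            f"{max_invalid_frac:.0%} repair limit; trace rejected"
        )
    if frac_bad == 0:
        return trace
    idx = np.arange(len(trace))
    good = trace.valid & np.isfinite(trace.diameter)
    filled = np.interp(idx, idx[good], trace.diameter[good])
    return PupilTrace(
        fs=trace.fs,
        diameter=filled,
        valid=trace.valid.copy(),
        ellipse_params=trace.ellipse_params,
        t0=trace.t0,
    )
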