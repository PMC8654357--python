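"""Core time-series containers shared across the pipeline.

Two kinds of uniformly sampled traces flow through the analysis: raw
two-channel fluorescence from one fiber (465 nm calcium-dependent and,
optionally, 405 nm calcium-independent) and per-frame pupil diameter from
the eye camera.  Both carry their own sample rate and session-time origin so
that event timestamps (always in session seconds) can be mapped to sample
indices without external bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["FluorescenceTrace", "DffTrace", "PupilTrace"]


@dataclass
class FluorescenceTrace:
    """Raw demodulated fluorescence from a single fiber.

    Parameters
    ----------
    fs : float
        Sample rate in Hz (nominally 1017 Hz for the lock-in output).
    values_465 : ndarray
        Calcium-dependent fluorescence, arbitrary units.
    values_405 : ndarray, optional
        Calcium-independent (isosbestic) channel.  Carried through I/O for
        QC; not used for signal correction.
    fiber_id : str
        Site label, e.g. ``"HDB"`` or ``"GP/SI"``.
    t0 : float
        Session time of the first sample, seconds.
    """

    fs: float
    values_465: np.ndarray
    values_405: np.ndarray | None = None
    fiber_id: str = ""
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values_465 = np.asarray(self.values_465, dtype=float)
        if self.values_405 is not None:
            self.values_405 = np.asarray(self.values_405, dtype=float)
            if self.values_405.shape != self.values_465.shape:
                raise ValueError("405 and 465 channels must have equal length")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.values_465.ndim != 1 or self.values_465.size < 1:
            raise ValueError("values_465 must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.values_465)):
            raise ValueError("fluorescence values must be finite")

    def __len__(self) -> int:
        return self.values_465.size

    @property
    def times(self) -> np.ndarray:
        """Session time of each sample, seconds."""
        return self.t0 + np.arange(len(self)) / self.fs


@dataclass
class DffTrace:
    """Fractional fluorescence change ΔF/F₀ (optionally z-scored).

    ``baseline_stats`` holds the (mean, sd) used for z-scoring so the raw
    ΔF/F₀ can always be recovered exactly.
    """

    fs: float
    dff: np.ndarray
    t0: float = 0.0
    fiber_id: str = ""
    zscored: bool = False
    baseline_stats: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.dff = np.asarray(self.dff, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.zscored:
            if self.baseline_stats is None or self.baseline_stats[1] <= 0:
                raise ValueError("z-scored trace requires baseline sd > 0")

    def __len__(self) -> int:
        return self.dff.size

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self)) / self.fs

    def with_values(self, dff: np.ndarray, **changes) -> "DffTrace":
        """Copy of this trace with new sample values (metadata preserved)."""
        return replace(self, dff=np.asarray(dff, dtype=float), **changes)

    def index_of(self, time_s: float) -> int:
        """Nearest sample index for a session time."""
        return int(round((time_s - self.t0) * self.fs))


@dataclass
class PupilTrace:
    """Area-equivalent pupil diameter per video frame.

    ``valid`` flags frames where segmentation succeeded; ``ellipse_params``
    optionally keeps the per-frame fit ``(xc, yc, a, b, theta)``.
    """

    fs: float
    diameter: np.ndarray
    valid: np.ndarray | None = None
    ellipse_params: np.ndarray | None = None
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.diameter = np.asarray(self.diameter, dtype=float)
        if self.valid is None:
            self.valid = np.ones(self.diameter.size, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.shape != self.diameter.shape:
            raise ValueError("valid flags must match diameter length")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    def __len__(self) -> int:
        return self.diameter.size

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self)) / self.fs

    @property
    def fraction_invalid(self) -> float:
        return float(np.mean(~self.valid)) if len(self) else 0.0
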