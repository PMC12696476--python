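"""Per-frame kinematic series derived from calibrated tracks.

Speeds and headings come from forward finite differences: the value at
frame ``t`` describes the displacement from ``t`` to ``t+1`` and is
undefined (NaN) whenever either endpoint is missing; the last frame is
always undefined.  Headings below a minimum-step threshold are also
undefined, so sub-pixel tracking jitter yields "no heading" rather than
a noisy one.  All angular outputs are unsigned degrees in [0, 180].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AlignmentError, InsufficientDataError, MissingDataError, ParameterError
from .traj_io import Track

DEFAULT_MIN_STEP_CM = 0.05


@dataclass(frozen=True)
class SpeedBand:
    """Empirical speed percentile band (cm/s), e.g. the 5th-20th
    percentile band of one female's within-trial speed distribution used
    by the glide classifier."""

    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not (0 <= self.lower <= self.upper):
            raise ParameterError(f"invalid speed band ({self.lower}, {self.upper})")

    def contains(self, speed: np.ndarray | float) -> np.ndarray | bool:
        """Inclusive membership; NaN speeds are outside."""
        s = np.asarray(speed, dtype=float)
        res = (s >= self.lower) & (s <= self.upper)
        return bool(res) if np.isscalar(speed) else res


def smooth_positions(track: Track, window_frames: int) -> Track:
    """Centred moving-average smoothing of x/y over available frames.

    Optional pre-processing before differencing; window 1 (or 0) is a
    no-op.  Frames without a position stay missing; the average is taken
    over the available frames inside the window.
    """
    if window_frames <= 1:
        return track.copy()
    out = track.copy()
    half = window_frames // 2
    have = track.has_position
    for arr_name in ("x", "y"):
        src = getattr(track, arr_name)
        dst = getattr(out, arr_name)
        for f in np.nonzero(have)[0]:
            lo, hi = max(0, f - half), min(track.n_frames, f + half + 1)
            vals = src[lo:hi][have[lo:hi]]
            dst[f] = float(np.mean(vals))
    return out


def frame_speeds(track: Track, fps: float) -> np.ndarray:
    """Per-frame speed (cm/s): ``|p[t+1] - p[t]| * fps`` at frame t.

    NaN across missing frames and at the last frame.
    """
    if fps <= 0:
        raise ParameterError(f"fps must be > 0, got {fps}")
    dx = np.diff(track.x)
    dy = np.diff(track.y)
    speed = np.full(track.n_frames, np.nan)
    speed[:-1] = np.hypot(dx, dy) * fps
    return speed


def headings(track: Track, min_step_cm: float = DEFAULT_MIN_STEP_CM) -> np.ndarray:
    """Per-frame heading (radians in (-pi, pi]) of the displacement
    t -> t+1; NaN where the displacement is shorter than ``min_step_cm``
    or either endpoint is missing."""
    if min_step_cm < 0:
        raise ParameterError(f"min_step_cm must be >= 0, got {min_step_cm}")
    dx = np.diff(track.x)
    dy = np.diff(track.y)
    step = np.hypot(dx, dy)
    h = np.full(track.n_frames, np.nan)
    with np.errstate(invalid="ignore"):
        ok = step >= min_step_cm
    ang = np.arctan2(dy, dx)
    h[:-1] = np.where(ok, ang, np.nan)
    return h


def pair_distance(a: Track, b: Track) -> np.ndarray:
    """Per-frame Euclidean distance (cm); NaN if either fish is missing."""
    if a.n_frames != b.n_frames:
        raise AlignmentError(
            f"tracks differ in frame count ({a.n_frames} vs {b.n_frames})"
        )
    return np.hypot(a.x - b.x, a.y - b.y)


def angle_between(heading_a: np.ndarray | float, heading_b: np.ndarray | float) -> np.ndarray | float:
    """Absolute angular difference of two headings, degrees in [0, 180].

    NaN inputs propagate to NaN outputs.
    """
    a = np.asarray(heading_a, dtype=float)
    b = np.asarray(heading_b, dtype=float)
    diff = np.angle(np.exp(1j * (a - b)))  # wrapped to (-pi, pi]
    out = np.degrees(np.abs(diff))
    if np.isscalar(heading_a) and np.isscalar(heading_b):
        return float(out)
    return out


def bearing_angle(
    from_x: np.ndarray | float,
    from_y: np.ndarray | float,
    heading: np.ndarray | float,
    to_x: np.ndarray | float,
    to_y: np.ndarray | float,
) -> np.ndarray | float:
    """Angle (degrees, [0, 180]) between an individual's heading and the
    line of sight from its position to a target position.

    0 means heading straight at the target, 180 directly away.  NaN when
    the heading is undefined or the positions coincide.
    """
    scalar = all(np.isscalar(v) for v in (from_x, from_y, heading, to_x, to_y))
    vx = np.asarray(to_x, dtype=float) - np.asarray(from_x, dtype=float)
    vy = np.asarray(to_y, dtype=float) - np.asarray(from_y, dtype=float)
    los = np.arctan2(vy, vx)
    out = np.asarray(angle_between(los, np.asarray(heading, dtype=float)), dtype=float)
    coincident = (vx == 0) & (vy == 0)
    out = np.where(coincident, np.nan, out)
    return float(out) if scalar else out


def speed_percentile_band(
    speeds: np.ndarray,
    lo_pct: float = 5.0,
    hi_pct: float = 20.0,
    min_samples: int = 20,
) -> SpeedBand:
    """Empirical percentile band over the defined (non-NaN) speeds.

    Percentiles use linear interpolation between closest order
    statistics.  Raises when fewer than ``min_samples`` speeds are
    defined — a band estimated from a handful of frames is meaningless.
    """
    s = np.asarray(speeds, dtype=float)
    s = s[~np.isnan(s)]
    if s.size < min_samples:
        raise InsufficientDataError(
            f"need >= {min_samples} defined speed samples, got {s.size}"
        )
    lo, hi = np.percentile(s, [lo_pct, hi_pct])
    return SpeedBand(lower=float(lo), upper=float(hi))


def estimate_body_length(track: Track) -> float:
    """Mean body length (cm) as the average bounding-box diagonal
    ``sqrt(w^2 + h^2)`` over frames with a box."""
    if track.bbox_w is None or track.bbox_h is None:
        raise MissingDataError(
            f"track {track.individual_id!r} carries no bounding-box data"
        )
    diag = np.hypot(track.bbox_w, track.bbox_h)
    diag = diag[~np.isnan(diag)]
    if diag.size == 0:
        raise MissingDataError(
            f"track {track.individual_id!r} has no frames with a bounding box"
        )
    return float(np.mean(diag))
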