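"""Literal per-frame reference implementations of the classifiers.

These functions evaluate the association / chase / glide predicates
frame by frame with plain ``math`` scalar arithmetic — no vectorization,
no shared helpers with :mod:`courtrack.events` — and serve as executable
documentation and as an independent check that the vectorized
classifiers implement exactly the stated per-frame rules.  They are
deliberately slow; use :mod:`courtrack.events` for real work.
"""

from __future__ import annotations

import math

from .events import ClassifierThresholds
from .traj_io import Track, Trial


def _pos(t: Track, f: int) -> tuple[float, float] | None:
    x, y = t.x[f], t.y[f]
    if math.isnan(x) or math.isnan(y):
        return None
    return float(x), float(y)


def _heading(t: Track, f: int, min_step_cm: float) -> float | None:
    """Heading of displacement f -> f+1, or None when undefined."""
    if f + 1 >= t.n_frames:
        return None
    p0, p1 = _pos(t, f), _pos(t, f + 1)
    if p0 is None or p1 is None:
        return None
    dx, dy = p1[0] - p0[0], p1[1] - p0[1]
    if math.hypot(dx, dy) < min_step_cm:
        return None
    return math.atan2(dy, dx)


def _speed(t: Track, f: int, fps: float) -> float | None:
    if f + 1 >= t.n_frames:
        return None
    p0, p1 = _pos(t, f), _pos(t, f + 1)
    if p0 is None or p1 is None:
        return None
    return math.hypot(p1[0] - p0[0], p1[1] - p0[1]) * fps


def _angle_diff_deg(a: float, b: float) -> float:
    d = math.degrees(abs(math.atan2(math.sin(a - b), math.cos(a - b))))
    return d


def _bearing_deg(
    fx: float, fy: float, heading: float, tx: float, ty: float
) -> float | None:
    if fx == tx and fy == ty:
        return None
    los = math.atan2(ty - fy, tx - fx)
    return _angle_diff_deg(los, heading)


def _percentile(sorted_vals: list[float], pct: float) -> float:
    """Linear interpolation between closest order statistics."""
    n = len(sorted_vals)
    if n == 1:
        return sorted_vals[0]
    rank = pct / 100.0 * (n - 1)
    lo = int(math.floor(rank))
    hi = min(lo + 1, n - 1)
    frac = rank - lo
    return sorted_vals[lo] * (1 - frac) + sorted_vals[hi] * frac


def association_frames_reference(
    trial: Trial,
    female: Track,
    thresholds: ClassifierThresholds = ClassifierThresholds(),
) -> list[bool]:
    male = trial.male
    out = []
    for f in range(trial.n_frames):
        pm, pf = _pos(male, f), _pos(female, f)
        if pm is None or pf is None:
            out.append(False)
            continue
        d = math.hypot(pm[0] - pf[0], pm[1] - pf[1])
        out.append(d < thresholds.association_radius_cm)
    return out


def chase_frames_reference(
    trial: Trial,
    female: Track,
    thresholds: ClassifierThresholds = ClassifierThresholds(),
) -> list[bool]:
    male = trial.male
    out = []
    for f in range(trial.n_frames):
        pm, pf = _pos(male, f), _pos(female, f)
        if pm is None or pf is None:
            out.append(False)
            continue
        d = math.hypot(pm[0] - pf[0], pm[1] - pf[1])
        if not d < thresholds.chase_distance_cm:
            out.append(False)
            continue
        hm = _heading(male, f, thresholds.min_step_cm)
        hf = _heading(female, f, thresholds.min_step_cm)
        if hm is None or hf is None:
            out.append(False)
            continue
        if not _angle_diff_deg(hm, hf) < thresholds.chase_align_deg:
            out.append(False)
            continue
        bearing = _bearing_deg(pf[0], pf[1], hf, pm[0], pm[1])
        out.append(bearing is not None and bearing > 90.0)
    return out


def glide_frames_reference(
    trial: Trial,
    female: Track,
    thresholds: ClassifierThresholds = ClassifierThresholds(),
) -> list[bool]:
    male = trial.male
    fps = trial.calibration.fps
    # band over the female's originally tracked speeds, whole trial
    band_speeds = []
    for f in range(trial.n_frames - 1):
        if bool(female.tracked[f]) and bool(female.tracked[f + 1]):
            s = _speed(female, f, fps)
            if s is not None:
                band_speeds.append(s)
    band_speeds.sort()
    lo_pct, hi_pct = thresholds.glide_speed_pcts
    lo = _percentile(band_speeds, lo_pct)
    hi = _percentile(band_speeds, hi_pct)

    out = []
    for f in range(trial.n_frames):
        pm, pf = _pos(male, f), _pos(female, f)
        if pm is None or pf is None:
            out.append(False)
            continue
        d = math.hypot(pm[0] - pf[0], pm[1] - pf[1])
        if not d <= thresholds.glide_radius_mm / 10.0:
            out.append(False)
            continue
        s = _speed(female, f, fps)
        if s is None or not (lo <= s <= hi):
            out.append(False)
            continue
        hf = _heading(female, f, thresholds.min_step_cm)
        if hf is None:
            out.append(False)
            continue
        bearing = _bearing_deg(pf[0], pf[1], hf, pm[0], pm[1])
        out.append(bearing is not None and bearing <= thresholds.glide_orient_deg)
    return out
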