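"""Trajectory classifiers for dyadic courtship events and bout merging.

Three frame-level classifiers, with the field's standard thresholds as
defaults:

* **association** — male within 4 cm (strictly) of a female; roughly two
  body lengths, the usual proximity criterion for association time in
  mate-choice assays.
* **chase** — male oriented *behind* the female, movement directions
  nearly parallel (male-female heading difference < 50 deg) and
  inter-individual distance < 3 cm.  "Behind" means the female-to-male
  line of sight makes an angle > 90 deg with her heading, i.e. the male
  projects onto the negative half of her heading axis.
* **glide** — slow, oriented female approach toward the male: distance
  <= 60 mm, her speed inside the 5th-20th percentile band of her own
  within-trial speed distribution, and her heading within 70 deg of the
  line of sight to the male.  Glide bouts separated by <= 3 s are merged
  into one event.

Maximal runs of positive frames of at least ``min_bout_frames`` become
half-open :class:`EventInterval` bouts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .errors import IntervalContractError, ParameterError, RoleError
from .kinematics import (
    DEFAULT_MIN_STEP_CM,
    SpeedBand,
    angle_between,
    bearing_angle,
    frame_speeds,
    headings,
    pair_distance,
    speed_percentile_band,
)
from .traj_io import Track, Trial

ASSOCIATION = "association"
CHASE = "chase"
GLIDE = "glide"


@dataclass(frozen=True)
class ClassifierThresholds:
    """Thresholds for the three classifiers (defaults as documented in
    the module docstring).  Distances in cm except ``glide_radius_mm``;
    angles in degrees; gaps in seconds."""

    association_radius_cm: float = 4.0
    chase_distance_cm: float = 3.0
    chase_align_deg: float = 50.0
    glide_radius_mm: float = 60.0
    glide_speed_pcts: tuple[float, float] = (5.0, 20.0)
    glide_orient_deg: float = 70.0
    glide_merge_gap_s: float = 3.0
    min_bout_frames: int = 3
    min_step_cm: float = DEFAULT_MIN_STEP_CM

    def __post_init__(self) -> None:
        positives = {
            "association_radius_cm": self.association_radius_cm,
            "chase_distance_cm": self.chase_distance_cm,
            "chase_align_deg": self.chase_align_deg,
            "glide_radius_mm": self.glide_radius_mm,
            "glide_orient_deg": self.glide_orient_deg,
        }
        for name, v in positives.items():
            if not v > 0:
                raise ParameterError(f"{name} must be > 0, got {v}")
        if self.glide_merge_gap_s < 0:
            raise ParameterError("glide_merge_gap_s must be >= 0")
        if self.min_bout_frames < 1:
            raise ParameterError("min_bout_frames must be >= 1")
        lo, hi = self.glide_speed_pcts
        if not (0 <= lo <= hi <= 100):
            raise ParameterError(f"invalid glide_speed_pcts {self.glide_speed_pcts}")
        if self.chase_distance_cm >= self.association_radius_cm:
            warnings.warn(
                "chase_distance_cm >= association_radius_cm: chase frames "
                "will not be contained in association frames",
                stacklevel=2,
            )

    @property
    def glide_radius_cm(self) -> float:
        return self.glide_radius_mm / 10.0


@dataclass(frozen=True)
class EventInterval:
    """One behavioral bout with half-open frame bounds [start, end)."""

    event_type: str
    actor_id: str
    target_id: str
    start_frame: int
    end_frame: int
    duration_s: float

    def __post_init__(self) -> None:
        if not self.start_frame < self.end_frame:
            raise IntervalContractError(
                f"empty interval [{self.start_frame}, {self.end_frame})"
            )

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame


def runs_from_mask(mask: np.ndarray, min_frames: int = 1) -> list[tuple[int, int]]:
    """Maximal runs of True of length >= min_frames, as half-open pairs."""
    m = np.asarray(mask, dtype=bool)
    if m.size == 0:
        return []
    d = np.diff(m.astype(np.int8))
    starts = list(np.nonzero(d == 1)[0] + 1)
    ends = list(np.nonzero(d == -1)[0] + 1)
    if m[0]:
        starts.insert(0, 0)
    if m[-1]:
        ends.append(m.size)
    return [(s, e) for s, e in zip(starts, ends) if e - s >= min_frames]


def _intervals_from_mask(
    mask: np.ndarray,
    event_type: str,
    actor_id: str,
    target_id: str,
    fps: float,
    min_frames: int,
) -> list[EventInterval]:
    return [
        EventInterval(
            event_type=event_type,
            actor_id=actor_id,
            target_id=target_id,
            start_frame=s,
            end_frame=e,
            duration_s=(e - s) / fps,
        )
        for s, e in runs_from_mask(mask, min_frames)
    ]


def _resolve_female(trial: Trial, female: Track | str | None) -> Track:
    if isinstance(female, Track):
        return female
    if isinstance(female, str):
        try:
            return trial.track_for_role(female)
        except RoleError:
            return trial.track_for_id(female)
    females = trial.females
    if len(females) != 1:
        raise RoleError(
            f"trial {trial.trial_id!r} has {len(females)} females; "
            "designate one by role or id"
        )
    return females[0]


def association_frames(
    trial: Trial,
    female: Track | str | None = None,
    thresholds: ClassifierThresholds = ClassifierThresholds(),
) -> tuple[np.ndarray, float, int]:
    """Association classifier: male strictly within the association
    radius of the female.

    Returns ``(per-frame boolean, total seconds, frame count)``.  Frames
    where either fish is missing are negative: no position, no evidence
    of proximity.
    """
    fem = _resolve_female(trial, female)
    dist = pair_distance(trial.male, fem)
    with np.errstate(invalid="ignore"):
        mask = dist < thresholds.association_radius_cm
    mask &= ~np.isnan(dist)
    count = int(np.count_nonzero(mask))
    return mask, count / trial.calibration.fps, count


def chase_mask(
    trial: Trial,
    female: Track | str | None = None,
    thresholds: ClassifierThresholds = ClassifierThresholds(),
) -> np.ndarray:
    """Per-frame chase predicate (see module docstring).  Frames with an
    undefined heading for either fish are negative, never errors."""
    fem = _resolve_female(trial, female)
    male = trial.male
    dist = pair_distance(male, fem)
    h_m = headings(male, thresholds.min_step_cm)
    h_f = headings(fem, thresholds.min_step_cm)
    align = angle_between(h_m, h_f)
    behind = bearing_angle(fem.x, fem.y, h_f, male.x, male.y)
    with np.errstate(invalid="ignore"):
        mask = (
            (dist < thresholds.chase_distance_cm)
            & (align < thresholds.chase_align_deg)
            & (behind > 90.0)
        )
    return mask & ~np.isnan(dist) & ~np.isnan(align) & ~np.isnan(behind)


def detect_chase(
    trial: Trial,
    female: Track | str | None = None,
    thresholds: ClassifierThresholds = ClassifierThresholds(),
    merge_gap_s: float = 0.0,
) -> list[EventInterval]:
    """Chase bouts: maximal runs of chase-positive frames of at least
    ``min_bout_frames``.  Bout merging is off by default for chases;
    pass ``merge_gap_s > 0`` to merge bouts across short gaps."""
    fem = _resolve_female(trial, female)
    mask = chase_mask(trial, fem, thresholds)
    events = _intervals_from_mask(
        mask,
        CHASE,
        trial.male.individual_id,
        fem.individual_id,
        trial.calibration.fps,
        thresholds.min_bout_frames,
    )
    if merge_gap_s > 0:
        events = merge_intervals(events, merge_gap_s, trial.calibration.fps)
    return events


def chase_seconds(
    trial: Trial,
    female: Track | str | None = None,
    thresholds: ClassifierThresholds = ClassifierThresholds(),
) -> float:
    """Total chase time in seconds (summed bout frames / fps)."""
    events = detect_chase(trial, female, thresholds)
    return sum(ev.n_frames for ev in events) / trial.calibration.fps


def glide_speed_band(
    trial: Trial,
    female: Track | str | None = None,
    thresholds: ClassifierThresholds = ClassifierThresholds(),
) -> SpeedBand:
    """Speed band for the glide classifier: empirical percentiles of the
    female's speed distribution over originally tracked frames of the
    whole trial (interpolated frames are excluded)."""
    fem = _resolve_female(trial, female)
    speeds = frame_speeds(fem, trial.calibration.fps)
    orig = fem.tracked.copy()
    orig[:-1] &= fem.tracked[1:]  # speed at t needs original fixes at t and t+1
    orig[-1] = False
    speeds = np.where(orig, speeds, np.nan)
    lo, hi = thresholds.glide_speed_pcts
    return speed_percentile_band(speeds, lo, hi)


def glide_mask(
    trial: Trial,
    female: Track | str | None = None,
    thresholds: ClassifierThresholds = ClassifierThresholds(),
    band: SpeedBand | None = None,
) -> tuple[np.ndarray, SpeedBand]:
    """Per-frame glide predicate for one female (see module docstring)."""
    fem = _resolve_female(trial, female)
    male = trial.male
    if band is None:
        band = glide_speed_band(trial, fem, thresholds)
    dist = pair_distance(male, fem)
    speeds = frame_speeds(fem, trial.calibration.fps)
    h_f = headings(fem, thresholds.min_step_cm)
    orient = bearing_angle(fem.x, fem.y, h_f, male.x, male.y)
    with np.errstate(invalid="ignore"):
        mask = (
            (dist <= thresholds.glide_radius_cm)
            & band.contains(speeds)
            & (orient <= thresholds.glide_orient_deg)
        )
    mask &= ~np.isnan(dist) & ~np.isnan(speeds) & ~np.isnan(orient)
    return mask, band


def detect_glides(
    trial: Trial,
    female: Track | str | None = None,
    thresholds: ClassifierThresholds = ClassifierThresholds(),
    band: SpeedBand | None = None,
) -> tuple[list[EventInterval], int]:
    """Glide events for one female: positive runs of at least
    ``min_bout_frames`` frames, then events separated by gaps of at most
    ``glide_merge_gap_s`` merged into one.  Returns (events, count)."""
    fem = _resolve_female(trial, female)
    mask, _ = glide_mask(trial, fem, thresholds, band)
    events = _intervals_from_mask(
        mask,
        GLIDE,
        fem.individual_id,
        trial.male.individual_id,
        trial.calibration.fps,
        thresholds.min_bout_frames,
    )
    events = merge_intervals(events, thresholds.glide_merge_gap_s, trial.calibration.fps)
    return events, len(events)


def merge_intervals(
    intervals: list[EventInterval], max_gap_s: float, fps: float
) -> list[EventInterval]:
    """Merge same-stream events separated by gaps of at most
    ``max_gap_s`` seconds.

    Chains whose successive gaps are each <= ``max_gap_s`` collapse into
    a single interval from the first start to the last end.  Idempotent;
    the output count is non-increasing in ``max_gap_s``.  The input must
    be one sorted, disjoint stream (one event type / actor / target).
    """
    if max_gap_s < 0:
        raise ParameterError(f"max_gap_s must be >= 0, got {max_gap_s}")
    if not intervals:
        return []
    key = (intervals[0].event_type, intervals[0].actor_id, intervals[0].target_id)
    for prev, cur in zip(intervals, intervals[1:]):
        if (cur.event_type, cur.actor_id, cur.target_id) != key:
            raise IntervalContractError("merge_intervals requires a single stream")
        if cur.start_frame < prev.end_frame:
            raise IntervalContractError(
                f"intervals unsorted or overlapping at frame {cur.start_frame}"
            )
    merged: list[EventInterval] = [intervals[0]]
    for cur in intervals[1:]:
        prev = merged[-1]
        gap_s = (cur.start_frame - prev.end_frame) / fps
        if gap_s <= max_gap_s:
            merged[-1] = replace(
                prev,
                end_frame=cur.end_frame,
                duration_s=(cur.end_frame - prev.start_frame) / fps,
            )
        else:
            merged.append(cur)
    return merged
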