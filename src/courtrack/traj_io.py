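"""Read, calibrate, gap-fill and quality-screen raw tracking tables.

The raw input is an idTracker-style delimited table with one row per
(frame, individual): columns ``frame, id, x, y`` and optionally
``bbox_w, bbox_h`` in pixels.  This module densifies those rows into
per-frame arrays (absent frames flagged missing), converts pixels to
centimetres, optionally fills short tracking dropouts by linear
interpolation, and screens trials against the tracked-frame quality
threshold (trials with fewer than 80% tracked frames are discarded;
exactly 80% is retained).

Conventions: frame indices are 0-based, positions are continuous cm in
an arena-centred frame once calibrated, intervals are half-open
``[start, end)``.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    EmptyTrialError,
    FormatError,
    ParameterError,
    RoleError,
)

MALE = "male"
FEMALE = "female"
FEMALE_RECEPTIVE = "female_receptive"
FEMALE_NONRECEPTIVE = "female_nonreceptive"

ROLES = frozenset({MALE, FEMALE, FEMALE_RECEPTIVE, FEMALE_NONRECEPTIVE})
FEMALE_ROLES = frozenset({FEMALE, FEMALE_RECEPTIVE, FEMALE_NONRECEPTIVE})

DICHOTOMOUS = "dichotomous"
NO_CHOICE = "no_choice"


@dataclass(frozen=True)
class CalibrationSpec:
    """Spatial and temporal calibration of one trial.

    Parameters
    ----------
    px_per_cm
        Pixel-to-centimetre scale of the video.  May be derived as
        (arena pixel diameter) / ``arena_diameter_cm`` via
        :meth:`from_arena_px`.
    arena_diameter_cm
        Diameter of the circular test arena, default 47 cm.
    fps
        Video frame rate, default 30 frames/s.
    trial_duration_s
        Nominal recording length, default 900 s (15 min).
    """

    px_per_cm: float = 1.0
    arena_diameter_cm: float = 47.0
    fps: float = 30.0
    trial_duration_s: float = 900.0

    def __post_init__(self) -> None:
        if not self.px_per_cm > 0:
            raise ParameterError(f"px_per_cm must be > 0, got {self.px_per_cm}")
        if not self.fps > 0:
            raise ParameterError(f"fps must be > 0, got {self.fps}")
        if not self.arena_diameter_cm > 0:
            raise ParameterError(
                f"arena_diameter_cm must be > 0, got {self.arena_diameter_cm}"
            )
        if not self.trial_duration_s > 0:
            raise ParameterError(
                f"trial_duration_s must be > 0, got {self.trial_duration_s}"
            )

    @property
    def arena_radius_cm(self) -> float:
        return self.arena_diameter_cm / 2.0

    @property
    def n_frames_nominal(self) -> int:
        return int(round(self.trial_duration_s * self.fps))

    @classmethod
    def from_arena_px(
        cls, arena_diameter_px: float, arena_diameter_cm: float = 47.0, **kwargs
    ) -> "CalibrationSpec":
        """Derive the pixel scale from the arena's apparent pixel diameter."""
        return cls(
            px_per_cm=arena_diameter_px / arena_diameter_cm,
            arena_diameter_cm=arena_diameter_cm,
            **kwargs,
        )


@dataclass
class Track:
    """Dense per-frame trajectory of one individual, in centimetres.

    ``x``/``y`` hold NaN wherever no position is available.  ``tracked``
    marks frames with an *original* detection; linearly interpolated
    frames carry a position but ``tracked`` stays False and
    ``interpolated`` becomes True, so quality statistics count only
    genuinely tracked frames.
    """

    individual_id: str
    role: str
    x: np.ndarray
    y: np.ndarray
    bbox_w: np.ndarray | None = None
    bbox_h: np.ndarray | None = None
    tracked: np.ndarray = field(default=None)  # type: ignore[assignment]
    interpolated: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise RoleError(f"unknown role {self.role!r}; expected one of {sorted(ROLES)}")
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        n = self.x.shape[0]
        if self.y.shape[0] != n:
            raise AlignmentError("x and y arrays differ in length")
        if self.tracked is None:
            self.tracked = ~(np.isnan(self.x) | np.isnan(self.y))
        self.tracked = np.asarray(self.tracked, dtype=bool)
        if self.interpolated is None:
            self.interpolated = np.zeros(n, dtype=bool)
        self.interpolated = np.asarray(self.interpolated, dtype=bool)
        for name in ("bbox_w", "bbox_h"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if arr.shape[0] != n:
                    raise AlignmentError(f"{name} length differs from x/y")
                setattr(self, name, arr)
        for name in ("tracked", "interpolated"):
            if getattr(self, name).shape[0] != n:
                raise AlignmentError(f"{name} length differs from x/y")

    @property
    def n_frames(self) -> int:
        return int(self.x.shape[0])

    @property
    def has_position(self) -> np.ndarray:
        """Frames with a usable position (tracked or interpolated)."""
        return ~(np.isnan(self.x) | np.isnan(self.y))

    @property
    def missing(self) -> np.ndarray:
        """Frames with no position at all."""
        return ~self.has_position

    @property
    def is_female(self) -> bool:
        return self.role in FEMALE_ROLES

    def copy(self) -> "Track":
        return Track(
            individual_id=self.individual_id,
            role=self.role,
            x=self.x.copy(),
            y=self.y.copy(),
            bbox_w=None if self.bbox_w is None else self.bbox_w.copy(),
            bbox_h=None if self.bbox_h is None else self.bbox_h.copy(),
            tracked=self.tracked.copy(),
            interpolated=self.interpolated.copy(),
        )


@dataclass
class Trial:
    """One behavioral assay: a male with one or two stimulus females.

    ``design`` is ``"dichotomous"`` (male + receptive + non-receptive
    female) or ``"no_choice"`` (male + one female).  ``metadata``
    carries treatment labels (``mixed_sex`` / ``male_only``), batch,
    rearing tank and time of testing where available.
    """

    trial_id: str
    design: str
    tracks: list[Track]
    calibration: CalibrationSpec
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.design not in (DICHOTOMOUS, NO_CHOICE, None):
            raise ParameterError(f"unknown design {self.design!r}")
        lengths = {t.n_frames for t in self.tracks}
        if len(lengths) > 1:
            raise AlignmentError(f"tracks differ in frame count: {sorted(lengths)}")
        if self.design is None:
            # raw track container (e.g. a single-individual fragment):
            # role composition not enforced
            return
        males = [t for t in self.tracks if t.role == MALE]
        females = [t for t in self.tracks if t.is_female]
        if len(males) != 1:
            raise RoleError(f"trial needs exactly 1 male track, got {len(males)}")
        if self.design == DICHOTOMOUS:
            froles = sorted(t.role for t in females)
            if froles != [FEMALE_NONRECEPTIVE, FEMALE_RECEPTIVE]:
                raise RoleError(
                    "dichotomous trial needs one receptive and one "
                    f"non-receptive female, got roles {froles}"
                )
        elif len(females) != 1:
            raise RoleError(
                f"no-choice trial needs exactly 1 female track, got {len(females)}"
            )

    @property
    def n_frames(self) -> int:
        return self.tracks[0].n_frames if self.tracks else 0

    @property
    def male(self) -> Track:
        return next(t for t in self.tracks if t.role == MALE)

    @property
    def females(self) -> list[Track]:
        return [t for t in self.tracks if t.is_female]

    def track_for_role(self, role: str) -> Track:
        for t in self.tracks:
            if t.role == role:
                return t
        raise RoleError(f"no track with role {role!r} in trial {self.trial_id!r}")

    def track_for_id(self, individual_id: str) -> Track:
        for t in self.tracks:
            if t.individual_id == individual_id:
                return t
        raise RoleError(f"no track with id {individual_id!r} in trial {self.trial_id!r}")

    def check_in_arena(self, tolerance_cm: float = 1.0) -> bool:
        """True iff every available position lies within the arena circle
        (radius + tolerance), assuming arena-centred coordinates."""
        r_max = self.calibration.arena_radius_cm + tolerance_cm
        for t in self.tracks:
            ok = t.has_position
            r = np.hypot(t.x[ok], t.y[ok])
            if r.size and float(np.max(r)) > r_max:
                return False
        return True

    def copy(self) -> "Trial":
        return Trial(
            trial_id=self.trial_id,
            design=self.design,
            tracks=[t.copy() for t in self.tracks],
            calibration=self.calibration,
            metadata=dict(self.metadata),
        )


@dataclass(frozen=True)
class QualityReport:
    """Tracking-quality summary for one trial.

    ``tracked_fraction`` maps individual id to the fraction of frames
    with an original detection; ``trial_fraction`` aggregates across
    individuals (minimum by default); ``passed`` is True when the
    aggregate meets the retention threshold (>= 0.80 by default — the
    filter discards strictly-below-threshold trials).
    """

    trial_id: str
    tracked_fraction: dict
    trial_fraction: float
    threshold: float
    passed: bool


def read_trajectories(
    path: str | Path,
    calibration: CalibrationSpec,
    roles: Mapping[str, str],
    *,
    design: str | None = NO_CHOICE,
    trial_id: str | None = None,
    metadata: dict | None = None,
    n_frames: int | None = None,
    origin_px: tuple[float, float] | None = None,
) -> Trial:
    """Read a raw tracking table into a calibrated :class:`Trial`.

    Parameters
    ----------
    path
        Delimited text file (comma or tab separated) with header
        ``frame,id,x,y[,bbox_w,bbox_h]``; one row per (frame,
        individual).  Frames need not be contiguous per individual —
        absent frames are flagged missing.
    calibration
        Pixel scale, frame rate and arena geometry.
    roles
        Map from individual id (as it appears in the file) to a role in
        ``{male, female, female_receptive, female_nonreceptive}``.
    n_frames
        Total frame count of the trial; defaults to ``max(frame) + 1``
        over all rows.
    origin_px
        Pixel coordinates of the arena centre.  When given it is
        subtracted before scaling, yielding arena-centred cm.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [str(c).strip() for c in df.columns]
    required = {"frame", "id", "x", "y"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"{path}: missing required columns {sorted(required - set(df.columns))}"
        )
    if df.duplicated(subset=["frame", "id"]).any():
        dup = df[df.duplicated(subset=["frame", "id"], keep=False)]
        raise FormatError(
            f"{path}: duplicate (frame, id) rows, e.g. "
            f"{dup[['frame', 'id']].iloc[0].tolist()}"
        )
    frames = df["frame"].to_numpy()
    if not np.issubdtype(frames.dtype, np.integer):
        if not np.allclose(frames, np.round(frames)):
            raise FormatError(f"{path}: non-integer frame indices")
        frames = np.round(frames).astype(int)
    if frames.size and frames.min() < 0:
        raise FormatError(f"{path}: negative frame index {frames.min()}")

    file_ids = [str(i) for i in pd.unique(df["id"])]
    roles = {str(k): v for k, v in roles.items()}
    unknown = [i for i in file_ids if i not in roles]
    if unknown:
        raise RoleError(f"{path}: individuals {unknown} not present in roles map")
    absent = [i for i in roles if i not in file_ids]
    if absent:
        raise RoleError(f"{path}: roles map names {absent} not present in the file")

    if n_frames is None:
        n_frames = int(frames.max()) + 1 if frames.size else 0
    if frames.size and frames.max() >= n_frames:
        raise FormatError(
            f"{path}: frame index {frames.max()} exceeds n_frames={n_frames}"
        )

    has_bbox = {"bbox_w", "bbox_h"}.issubset(df.columns)
    ox, oy = origin_px if origin_px is not None else (0.0, 0.0)
    scale = calibration.px_per_cm

    tracks: list[Track] = []
    id_series = df["id"].astype(str)
    for ind in file_ids:
        sub = df[id_series == ind]
        idx = np.round(sub["frame"].to_numpy(dtype=float)).astype(int)
        x = np.full(n_frames, np.nan)
        y = np.full(n_frames, np.nan)
        x[idx] = (sub["x"].to_numpy(dtype=float) - ox) / scale
        y[idx] = (sub["y"].to_numpy(dtype=float) - oy) / scale
        bw = bh = None
        if has_bbox:
            bw = np.full(n_frames, np.nan)
            bh = np.full(n_frames, np.nan)
            bw[idx] = sub["bbox_w"].to_numpy(dtype=float) / scale
            bh[idx] = sub["bbox_h"].to_numpy(dtype=float) / scale
        tracks.append(
            Track(individual_id=ind, role=roles[ind], x=x, y=y, bbox_w=bw, bbox_h=bh)
        )

    return Trial(
        trial_id=trial_id if trial_id is not None else path.stem,
        design=design,
        tracks=tracks,
        calibration=calibration,
        metadata=dict(metadata or {}),
    )


def write_trajectories(trial: Trial, path: str | Path) -> None:
    """Write a trial back to the raw table format (pixels), inverting the
    calibration.  Missing frames produce no row."""
    scale = trial.calibration.px_per_cm
    rows = []
    for t in trial.tracks:
        for f in np.nonzero(t.has_position)[0]:
            row = {
                "frame": int(f),
                "id": t.individual_id,
                "x": t.x[f] * scale,
                "y": t.y[f] * scale,
            }
            if t.bbox_w is not None and not math.isnan(t.bbox_w[f]):
                row["bbox_w"] = t.bbox_w[f] * scale
                row["bbox_h"] = t.bbox_h[f] * scale
            rows.append(row)
    pd.DataFrame(rows).sort_values(["frame", "id"]).to_csv(path, index=False)


def interpolate_gaps(trial: Trial, max_gap_s: float = 0.5) -> Trial:
    """Fill short tracking dropouts by linear interpolation.

    Missing runs of duration <= ``max_gap_s`` that are bounded by
    positions on both sides are filled; longer runs and leading/trailing
    gaps stay missing.  Filled frames are flagged ``interpolated`` and
    never count as tracked, so quality screening is unaffected.
    ``max_gap_s = 0`` returns the trial unchanged.
    """
    if max_gap_s < 0:
        raise ParameterError(f"max_gap_s must be >= 0, got {max_gap_s}")
    out = trial.copy()
    if max_gap_s == 0 or trial.n_frames == 0:
        return out
    max_gap_frames = int(math.floor(max_gap_s * trial.calibration.fps + 1e-9))
    if max_gap_frames < 1:
        return out
    for t in out.tracks:
        have = t.has_position
        if have.all() or not have.any():
            continue
        missing = ~have
        # runs of consecutive missing frames
        d = np.diff(missing.astype(np.int8))
        starts = list(np.nonzero(d == 1)[0] + 1)
        ends = list(np.nonzero(d == -1)[0] + 1)
        if missing[0]:
            starts.insert(0, 0)
        if missing[-1]:
            ends.append(t.n_frames)
        arrays = [t.x, t.y]
        if t.bbox_w is not None:
            arrays += [t.bbox_w, t.bbox_h]
        for s, e in zip(starts, ends):
            if s == 0 or e == t.n_frames or (e - s) > max_gap_frames:
                continue
            left, right = s - 1, e
            w = (np.arange(s, e) - left) / (right - left)
            for a in arrays:
                if math.isnan(a[left]) or math.isnan(a[right]):
                    continue
                a[s:e] = a[left] + w * (a[right] - a[left])
            t.interpolated[s:e] = True
    return out


def tracked_fraction(
    trial: Trial, threshold: float = 0.80, aggregate: str = "min"
) -> QualityReport:
    """Per-individual and trial-level tracked-frame fractions.

    Only originally tracked frames count (interpolation never improves
    quality).  ``passed`` is True when the aggregate fraction is >= the
    threshold: a trial at exactly 80% is retained, strictly below is
    discarded.  ``aggregate`` is ``"min"`` (default: the trial is only
    as good as its worst-tracked fish) or ``"mean"``.
    """
    if trial.n_frames == 0:
        raise EmptyTrialError(f"trial {trial.trial_id!r} has zero frames")
    per = {
        t.individual_id: float(np.count_nonzero(t.tracked)) / trial.n_frames
        for t in trial.tracks
    }
    if aggregate == "min":
        agg = min(per.values())
    elif aggregate == "mean":
        agg = float(np.mean(list(per.values())))
    else:
        raise ParameterError(f"unknown aggregate {aggregate!r}")
    return QualityReport(
        trial_id=trial.trial_id,
        tracked_fraction=per,
        trial_fraction=agg,
        threshold=threshold,
        passed=bool(agg >= threshold),
    )


def filter_by_quality(
    trials: Iterable[Trial], threshold: float = 0.80, aggregate: str = "min"
) -> tuple[list[Trial], list[QualityReport]]:
    """Keep trials whose aggregate tracked fraction meets the threshold.

    Returns the retained trials and the full list of quality reports
    (retained and rejected alike) for logging.
    """
    kept: list[Trial] = []
    reports: list[QualityReport] = []
    for trial in trials:
        rep = tracked_fraction(trial, threshold=threshold, aggregate=aggregate)
        reports.append(rep)
        if rep.passed:
            kept.append(trial)
    return kept, reports


def write_events_csv(
    events: Sequence, fps: float, path: str | Path, trial_id: str = ""
) -> None:
    """Write event intervals to the standard event CSV schema:
    ``trial_id, event_type, actor_id, target_id, start_frame, end_frame,
    start_s, duration_s`` with half-open frame bounds."""
    rows = [
        {
            "trial_id": trial_id,
            "event_type": ev.event_type,
            "actor_id": ev.actor_id,
            "target_id": ev.target_id,
            "start_frame": ev.start_frame,
            "end_frame": ev.end_frame,
            "start_s": ev.start_frame / fps,
            "duration_s": ev.duration_s,
        }
        for ev in events
    ]
    cols = [
        "trial_id",
        "event_type",
        "actor_id",
        "target_id",
        "start_frame",
        "end_frame",
        "start_s",
        "duration_s",
    ]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def write_trial_summary(records: Sequence, path: str | Path) -> None:
    """Write one row per assay.  ``records`` may be BehaviorRecord
    dataclasses or plain dicts; dataclasses are flattened by field."""
    rows = [
        dataclasses.asdict(r) if dataclasses.is_dataclass(r) else dict(r)
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
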