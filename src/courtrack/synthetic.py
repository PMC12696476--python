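"""Synthetic trials with scripted, ground-truth-labelled episodes, and
behavior-count tables with the statistical structure of the real assays.

Trajectory generator
--------------------
Each individual follows a discrete correlated random walk (heading
persistence plus per-frame speed draws), interrupted by scripted
episodes that realize the classifiers' predicates *by construction*:

* ``chase`` — the female travels a circular arc at moderate speed and
  the male is placed a fixed short distance behind her along her
  direction of motion (distance < 3 cm, heading difference ~ a few
  degrees, male strictly behind).
* ``glide`` — the male holds a fixed point while the female approaches
  it in a straight line from just inside 60 mm, at a speed placed
  inside her own 5th-20th speed-percentile band (see below), heading
  exactly at the male.
* ``approach_association`` — both fish hold nearly stationary positions
  within the association radius (no headings, so neither chase nor
  glide can fire).
* ``depart`` — the actor swims straight back toward its home region.

Band placement: wandering speed draws are fast (6-12 cm/s), each fish
intersperses short idle bouts at 0.3 cm/s (~8% of frames), and glides
run at 3.0 cm/s.  The idle block anchors the 5th percentile below the
glide speed and the wander block keeps the 20th percentile above it, so
scripted glide frames fall inside the female's empirical band.  Idle
steps are below the heading-definition threshold, so slow frames can
never produce glide or chase positives.

Outside scripted episodes the male wanders in a home half-disk on one
side of the arena and the females on the other, always more than the
largest classifier radius apart; between a scripted episode and the
resumption of wandering the actor jumps back to its home region.  At
zero noise, therefore, every classifier-positive frame is a scripted
frame — ground truth is exact, not approximate.  Truth labels are
assigned *before* positional jitter and frame dropout are applied, so
recovery-versus-noise curves are measurable.

Count generator
---------------
:func:`simulate_counts` draws per-assay behavior counts from a
log-linear negative-binomial model (fixed effects of female status,
male social treatment and their interaction, Gaussian random intercepts
for batch and rearing tank, and body-size / glide-frequency covariate
effects), zero-inflates chasing time, and draws censored exponential
latencies — the data-generating process assumed by the downstream
mixed-model battery, with the published effect sizes as defaults.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ScriptError
from .traj_io import (
    DICHOTOMOUS,
    FEMALE,
    FEMALE_NONRECEPTIVE,
    FEMALE_RECEPTIVE,
    MALE,
    NO_CHOICE,
    CalibrationSpec,
    Track,
    Trial,
)

WANDER_SPEED_RANGE = (6.0, 12.0)  # cm/s
IDLE_SPEED = 0.3                  # cm/s; step below heading threshold
GLIDE_SPEED = 3.0                 # cm/s; inside the 5th-20th pct band
CHASE_SPEED = 4.0                 # cm/s along the arc
CHASE_TRAIL_CM = 2.0              # male's distance behind the female
GLIDE_START_CM = 5.8              # just inside the 60 mm glide radius
WANDER_TURN_SD = 0.3              # rad/frame heading persistence
# bout lengths are drawn from narrow uniform ranges so every fish's
# idle-frame fraction stays between ~6% and ~10% of the trial: enough
# slow frames to anchor the 5th speed percentile below the glide speed,
# few enough that the 20th percentile stays in the fast wander block
WANDER_BOUT_RANGE_S = (8.0, 11.0)
IDLE_BOUT_RANGE_S = (0.7, 0.9)


@dataclass(frozen=True)
class Episode:
    """One scripted behavioral episode.

    ``actor_role`` performs the behavior; ``target_role`` receives it
    (None for solo kinds).  ``params`` can override the kind's kinematic
    defaults (speed, arc radius, start distance, ...).
    """

    kind: str  # wander | idle | approach_association | chase | glide | depart
    actor_role: str
    start_s: float
    duration_s: float
    target_role: str | None = None
    params: dict = field(default_factory=dict)

    KINDS = ("wander", "idle", "approach_association", "chase", "glide", "depart")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ScriptError(f"unknown episode kind {self.kind!r}")
        if self.duration_s <= 0 or self.start_s < 0:
            raise ScriptError("episode needs start_s >= 0 and duration_s > 0")
        if self.kind in ("chase", "glide", "approach_association") and self.target_role is None:
            raise ScriptError(f"{self.kind} episode needs a target_role")

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s

    def participants(self) -> tuple[str, ...]:
        if self.kind in ("chase", "glide", "approach_association"):
            return (self.actor_role, self.target_role)  # type: ignore[return-value]
        return (self.actor_role,)


@dataclass
class EpisodeScript:
    """Ordered episode schedule for one synthetic trial."""

    design: str
    episodes: list[Episode]
    duration_s: float = 900.0

    def __post_init__(self) -> None:
        self.episodes = sorted(self.episodes, key=lambda e: e.start_s)
        for ep in self.episodes:
            if ep.end_s > self.duration_s + 1e-9:
                raise ScriptError(
                    f"episode {ep.kind} at {ep.start_s}s runs past the "
                    f"{self.duration_s}s trial"
                )
        # no participant may be in two episodes at once
        busy: dict[str, float] = {}
        for ep in self.episodes:
            for role in ep.participants():
                if busy.get(role, -math.inf) > ep.start_s + 1e-9:
                    raise ScriptError(
                        f"overlapping episodes for role {role!r} at {ep.start_s}s"
                    )
                busy[role] = max(busy.get(role, -math.inf), ep.end_s)

    def glide_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for ep in self.episodes:
            if ep.kind == "glide":
                out[ep.actor_role] = out.get(ep.actor_role, 0) + 1
        return out

    def check_glide_spacing(self, min_gap_s: float) -> None:
        """Raise unless same-female glide episodes are separated by more
        than ``min_gap_s`` — otherwise merged event counts would not
        equal scripted counts."""
        by_actor: dict[str, list[Episode]] = {}
        for ep in self.episodes:
            if ep.kind == "glide":
                by_actor.setdefault(ep.actor_role, []).append(ep)
        for role, eps in by_actor.items():
            for a, b in zip(eps, eps[1:]):
                if b.start_s - a.end_s <= min_gap_s:
                    raise ScriptError(
                        f"glide episodes for {role!r} separated by "
                        f"{b.start_s - a.end_s:.2f}s <= merge gap {min_gap_s}s"
                    )


@dataclass
class SyntheticTruth:
    """Ground-truth ethogram of one simulated trial.

    Per-frame boolean label arrays keyed by individual id: ``chase`` for
    the male-toward-female stream, ``glide`` and ``association`` per
    female.  ``expected_glide_counts`` is the scripted (merge-aware)
    glide event count per female.
    """

    n_frames: int
    chase: dict
    glide: dict
    association: dict
    expected_glide_counts: dict
    chase_intervals: list


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement noise: isotropic Gaussian positional jitter (cm) and
    i.i.d. per-frame, per-individual dropout probability."""

    jitter_sd_cm: float = 0.0
    dropout_prob: float = 0.0


def _role_layout(design: str) -> dict[str, str]:
    """individual id -> role for each design."""
    if design == DICHOTOMOUS:
        return {"m1": MALE, "fr1": FEMALE_RECEPTIVE, "fn1": FEMALE_NONRECEPTIVE}
    if design == NO_CHOICE:
        return {"m1": MALE, "f1": FEMALE}
    raise ScriptError(f"unknown design {design!r}")


def make_standard_script(
    design: str = DICHOTOMOUS,
    duration_s: float = 900.0,
    n_chases: int = 4,
    n_glides_receptive: int = 5,
    n_glides_nonreceptive: int = 2,
    n_associations: int = 2,
    chase_s: float = 2.0,
    glide_s: float = 1.5,
    gap_s: float = 6.0,
) -> EpisodeScript:
    """Build a simple sequential schedule exercising every classifier.

    Since the male takes part in every episode kind, episodes are laid
    out one after another with ``gap_s`` of wandering in between (which
    also keeps same-female glides farther apart than the 3-s merge
    window).  Chases target the receptive female in dichotomous trials.
    """
    roles = _role_layout(design)
    females = [r for r in roles.values() if r != MALE]
    receptive = FEMALE_RECEPTIVE if design == DICHOTOMOUS else FEMALE
    nonreceptive = FEMALE_NONRECEPTIVE if design == DICHOTOMOUS else None

    episodes: list[Episode] = []
    t = gap_s
    def push(ep: Episode) -> None:
        nonlocal t
        episodes.append(ep)
        t = ep.end_s + gap_s

    # round-robin across streams so no stream is bunched at one end of
    # the trial (and same-female glides stay well separated)
    queues: list[list[tuple[str, str]]] = [
        [("chase", receptive)] * n_chases,
        [("glide", receptive)] * n_glides_receptive,
        [("glide", nonreceptive)] * (n_glides_nonreceptive if nonreceptive else 0),
        [
            ("approach_association", females[i % len(females)])
            for i in range(n_associations)
        ],
    ]
    kinds: list[tuple[str, str]] = []
    while any(queues):
        for q in queues:
            if q:
                kinds.append(q.pop(0))
    for kind, who in kinds:
        if kind == "chase":
            push(Episode("chase", MALE, t, chase_s, target_role=who))
        elif kind == "glide":
            push(Episode("glide", who, t, glide_s, target_role=MALE))
        else:
            push(Episode("approach_association", MALE, t, 3.0, target_role=who))
    if t > duration_s:
        raise ScriptError(
            f"standard script needs {t:.0f}s but trial is {duration_s}s"
        )
    return EpisodeScript(design=design, episodes=episodes, duration_s=duration_s)


def random_script(
    rng: np.random.Generator,
    design: str = DICHOTOMOUS,
    duration_s: float = 180.0,
    gap_s_range: tuple[float, float] = (4.0, 10.0),
) -> EpisodeScript:
    """Randomized episode schedule: episode kinds, targets, durations
    and spacings drawn from ``rng``, sequential (the male takes part in
    every kind) with gaps above the glide merge window."""
    roles = _role_layout(design)
    females = [r for r in roles.values() if r != MALE]
    episodes: list[Episode] = []
    t = float(rng.uniform(*gap_s_range))
    while True:
        kind = ["chase", "glide", "approach_association"][rng.integers(0, 3)]
        who = females[rng.integers(0, len(females))]
        dur = float(rng.uniform(1.0, 2.5)) if kind != "glide" else float(rng.uniform(0.5, 1.6))
        if t + dur + 1.0 > duration_s:
            break
        if kind == "glide":
            episodes.append(Episode("glide", who, t, dur, target_role=MALE))
        elif kind == "chase":
            episodes.append(Episode("chase", MALE, t, dur, target_role=who))
        else:
            episodes.append(Episode("approach_association", MALE, t, dur, target_role=who))
        t += dur + float(rng.uniform(*gap_s_range))
    return EpisodeScript(design=design, episodes=episodes, duration_s=duration_s)


class _Wanderer:
    """Correlated-random-walk state confined to a home half-disk, with
    alternating fast-wander and slow-idle bouts."""

    def __init__(self, home_xy: tuple[float, float], home_r: float, rng: np.random.Generator, fps: float):
        self.home = np.asarray(home_xy, dtype=float)
        self.home_r = home_r
        self.rng = rng
        self.fps = fps
        self.pos = self.home + self._random_offset()
        self.heading = rng.uniform(-math.pi, math.pi)
        self.mode = "wander"
        self.mode_left = self._bout_frames("wander")

    def _random_offset(self) -> np.ndarray:
        ang = self.rng.uniform(0, 2 * math.pi)
        rad = self.home_r * 0.8 * math.sqrt(self.rng.uniform())
        return np.array([rad * math.cos(ang), rad * math.sin(ang)])

    def _bout_frames(self, mode: str) -> int:
        lo, hi = WANDER_BOUT_RANGE_S if mode == "wander" else IDLE_BOUT_RANGE_S
        return max(1, int(round(self.rng.uniform(lo, hi) * self.fps)))

    def teleport_home(self) -> None:
        self.pos = self.home + self._random_offset()
        self.heading = self.rng.uniform(-math.pi, math.pi)

    def step(self) -> np.ndarray:
        if self.mode_left <= 0:
            self.mode = "idle" if self.mode == "wander" else "wander"
            self.mode_left = self._bout_frames(self.mode)
        self.mode_left -= 1
        if self.mode == "wander":
            speed = self.rng.uniform(*WANDER_SPEED_RANGE)
            self.heading += self.rng.normal(0.0, WANDER_TURN_SD)
        else:
            speed = IDLE_SPEED
            self.heading = self.rng.uniform(-math.pi, math.pi)
        step = speed / self.fps
        prop = self.pos + step * np.array([math.cos(self.heading), math.sin(self.heading)])
        if np.hypot(*(prop - self.home)) > self.home_r:
            # redirect toward home centre (reflective confinement)
            back = self.home - self.pos
            self.heading = math.atan2(back[1], back[0]) + self.rng.normal(0.0, 0.3)
            prop = self.pos + step * np.array([math.cos(self.heading), math.sin(self.heading)])
            if np.hypot(*(prop - self.home)) > self.home_r:
                prop = self.pos + step * back / max(np.hypot(*back), 1e-9)
        self.pos = prop
        return self.pos.copy()


def simulate_trial(
    script: EpisodeScript,
    calibration: CalibrationSpec | None = None,
    noise: NoiseSpec = NoiseSpec(),
    seed: int | tuple | np.random.SeedSequence = 0,
    trial_id: str = "synthetic",
    metadata: dict | None = None,
    merge_gap_s: float = 3.0,
) -> tuple[Trial, SyntheticTruth]:
    """Simulate one trial from an episode script.

    Deterministic given ``seed`` (any value accepted by
    ``numpy.random.default_rng``; pass ``(master_seed, trial_index)``
    for reproducible parallel batches).  Returns the noisy
    :class:`Trial` and the pre-noise :class:`SyntheticTruth`.
    """
    if calibration is None:
        calibration = CalibrationSpec()
    script.check_glide_spacing(merge_gap_s)
    rng = np.random.default_rng(seed)
    fps = calibration.fps
    n = int(round(script.duration_s * fps))
    roles = _role_layout(script.design)
    ids = list(roles)
    role_to_id = {r: i for i, r in roles.items()}

    arena_r = calibration.arena_radius_cm
    # home half-disks: male left, females right; gap exceeds every
    # classifier radius so unscripted frames are always negative
    home_r = min(7.0, arena_r * 0.30)
    cx = arena_r - home_r - 2.0
    # scripted episodes happen well inside the male's half: the whole
    # scripted zone stays > 6 cm (the largest classifier radius) away
    # from the females' home disks
    zone_cx = -(cx + home_r) / 2.0
    homes: dict[str, tuple[tuple[float, float], float]] = {role_to_id[MALE]: ((-cx, 0.0), home_r)}
    females = [i for i in ids if roles[i] != MALE]
    for k, fid in enumerate(females):
        dy = 0.0 if len(females) == 1 else (home_r + 0.5) * (1 if k == 0 else -1) * 0.9
        homes[fid] = ((cx, dy), min(home_r, arena_r - abs(dy) - home_r * 0.2))

    wanderers = {i: _Wanderer(homes[i][0], homes[i][1], rng, fps) for i in ids}
    pos = {i: np.full((n, 2), np.nan) for i in ids}
    scripted = {i: np.zeros(n, dtype=bool) for i in ids}

    chase_truth = {i: np.zeros(n, dtype=bool) for i in females}
    glide_truth = {i: np.zeros(n, dtype=bool) for i in females}
    chase_intervals: list[tuple[int, int, str]] = []

    def frames_of(ep: Episode) -> tuple[int, int]:
        s = int(round(ep.start_s * fps))
        e = min(n, int(round(ep.end_s * fps)))
        return s, e

    # scripted segments first (absolute geometry, independent of wander)
    for ep in script.episodes:
        s, e = frames_of(ep)
        if e <= s:
            continue
        k = np.arange(e - s)
        if ep.kind == "chase":
            fem = role_to_id[ep.target_role]
            male = role_to_id[MALE]
            radius = float(ep.params.get("radius_cm", 6.0))
            speed = float(ep.params.get("speed_cm_s", CHASE_SPEED))
            centre = np.array(ep.params.get("centre", (zone_cx, 0.0)))
            direction = 1.0 if rng.uniform() < 0.5 else -1.0
            phi0 = rng.uniform(0, 2 * math.pi)
            omega = direction * speed / (radius * fps)
            phi = phi0 + omega * k
            fx = centre[0] + radius * np.cos(phi)
            fy = centre[1] + radius * np.sin(phi)
            ux = -direction * np.sin(phi)
            uy = direction * np.cos(phi)
            pos[fem][s:e, 0], pos[fem][s:e, 1] = fx, fy
            pos[male][s:e, 0] = fx - CHASE_TRAIL_CM * ux
            pos[male][s:e, 1] = fy - CHASE_TRAIL_CM * uy
            scripted[fem][s:e] = True
            scripted[male][s:e] = True
            chase_truth[fem][s:e] = True
            chase_intervals.append((s, e, fem))
        elif ep.kind == "glide":
            fem = role_to_id[ep.actor_role]
            male = role_to_id[MALE]
            anchor = np.array(ep.params.get("anchor", (zone_cx, 0.0)))
            anchor = anchor + rng.uniform(-1.0, 1.0, size=2)
            speed = float(ep.params.get("speed_cm_s", GLIDE_SPEED))
            start_d = float(ep.params.get("start_cm", GLIDE_START_CM))
            psi = rng.uniform(0, 2 * math.pi)
            d = start_d - speed * k / fps
            d = np.maximum(d, 0.8)  # never overrun the male
            pos[fem][s:e, 0] = anchor[0] + d * math.cos(psi)
            pos[fem][s:e, 1] = anchor[1] + d * math.sin(psi)
            pos[male][s:e, 0] = anchor[0]
            pos[male][s:e, 1] = anchor[1]
            scripted[fem][s:e] = True
            scripted[male][s:e] = True
            glide_truth[fem][s:e] = True
        elif ep.kind == "approach_association":
            # both fish hold still within the association radius
            a = role_to_id[ep.actor_role]
            b = role_to_id[ep.target_role]
            anchor = np.array(ep.params.get("anchor", (zone_cx, 1.0)))
            dist = float(ep.params.get("distance_cm", 2.5))
            psi = rng.uniform(0, 2 * math.pi)
            pos[a][s:e, 0], pos[a][s:e, 1] = anchor[0], anchor[1]
            pos[b][s:e, 0] = anchor[0] + dist * math.cos(psi)
            pos[b][s:e, 1] = anchor[1] + dist * math.sin(psi)
            scripted[a][s:e] = True
            scripted[b][s:e] = True
        elif ep.kind == "depart":
            # handled in the chronological pass (needs current position)
            pass
        # explicit wander/idle episodes fall through to the default walk

    # chronological pass: fill unscripted frames with the confined walk
    for i in ids:
        w = wanderers[i]
        prev_scripted = False
        for f in range(n):
            if scripted[i][f]:
                prev_scripted = True
                continue
            if prev_scripted:
                w.teleport_home()
                prev_scripted = False
            pos[i][f] = w.step()

    # depart episodes overwrite with a straight run toward home
    for ep in script.episodes:
        if ep.kind != "depart":
            continue
        i = role_to_id[ep.actor_role]
        s, e = frames_of(ep)
        start = pos[i][s - 1] if s > 0 else pos[i][s]
        home = np.asarray(homes[i][0])
        speed = float(ep.params.get("speed_cm_s", 10.0))
        vec = home - start
        dist = float(np.hypot(*vec))
        u = vec / max(dist, 1e-9)
        k = np.arange(e - s, dtype=float)
        travelled = np.minimum(speed * (k + 1) / fps, dist)
        pos[i][s:e] = start + travelled[:, None] * u
        scripted[i][s:e] = True

    association_truth = {}
    male_id = role_to_id[MALE]
    for fid in females:
        dxy = pos[male_id] - pos[fid]
        dist = np.hypot(dxy[:, 0], dxy[:, 1])
        association_truth[fid] = dist < 4.0

    truth = SyntheticTruth(
        n_frames=n,
        chase={fid: chase_truth[fid] for fid in females},
        glide={fid: glide_truth[fid] for fid in females},
        association=association_truth,
        expected_glide_counts={
            role_to_id[r]: c for r, c in script.glide_counts().items()
        },
        chase_intervals=chase_intervals,
    )

    # measurement noise after truth labelling
    tracks = []
    for i in ids:
        xy = pos[i].copy()
        if noise.jitter_sd_cm > 0:
            xy += rng.normal(0.0, noise.jitter_sd_cm, size=xy.shape)
        tracked = np.ones(n, dtype=bool)
        if noise.dropout_prob > 0:
            drop = rng.uniform(size=n) < noise.dropout_prob
            xy[drop] = np.nan
            tracked[drop] = False
        body = 2.2 if roles[i] == MALE else 2.8  # cm, typical guppy sizes
        bw = np.where(tracked, body * 0.8, np.nan)
        bh = np.where(tracked, body * 0.6, np.nan)
        tracks.append(
            Track(
                individual_id=i,
                role=roles[i],
                x=xy[:, 0],
                y=xy[:, 1],
                bbox_w=bw,
                bbox_h=bh,
                tracked=tracked,
            )
        )
    trial = Trial(
        trial_id=trial_id,
        design=script.design,
        tracks=tracks,
        calibration=calibration,
        metadata=dict(metadata or {}),
    )
    return trial, truth


# --------------------------------------------------------------------------
# behavior-count simulation


def _cell_key(treatment: str, status: str) -> str:
    return f"{treatment}:{status}"


@dataclass(frozen=True)
class ResponseSpec:
    """Log-linear NB specification of one count response.

    ``baseline`` is the expected count in the reference cell (male-only
    rearing, non-receptive female, covariates at zero); the ``irr_*``
    fields are multiplicative effects (incidence-rate ratios) applied on
    the log link; ``dispersion`` is the NB size parameter theta
    (variance = mu + mu^2 / theta); ``zero_inflation`` is the extra
    probability mass at zero.
    """

    baseline: float
    irr_status: float = 1.0
    irr_treatment: float = 1.0
    irr_interaction: float = 1.0
    irr_body_size: float = 1.0
    irr_glide: float = 1.0
    dispersion: float = 2.0
    zero_inflation: float = 0.0


@dataclass
class CountSimConfig:
    """Study-level configuration of the count simulation.

    Defaults reproduce the published study conditions: the 105-assay
    no-choice layout (24 mixed-sex/receptive, 29 mixed-sex/
    non-receptive, 26 male-only/receptive, 26 male-only/non-receptive),
    response effect sizes equal to the published IRRs (e.g. the
    mixed-sex treatment multiplies sneak attempts by 2.45), an
    intercept-only zero-inflation term for chasing, and receptive
    females gliding more than non-receptive ones.
    """

    n_per_cell: dict = field(default_factory=lambda: {
        _cell_key("mixed_sex", "receptive"): 24,
        _cell_key("mixed_sex", "non_receptive"): 29,
        _cell_key("male_only", "receptive"): 26,
        _cell_key("male_only", "non_receptive"): 26,
    })
    responses: dict = field(default_factory=lambda: {
        "displays": ResponseSpec(
            baseline=15.91, irr_status=1.04, irr_treatment=1.10,
            irr_interaction=1.08, irr_body_size=1.08, irr_glide=1.00,
            dispersion=3.0,
        ),
        "sneaks": ResponseSpec(
            baseline=1.16, irr_status=1.64, irr_treatment=2.45,
            irr_interaction=0.54, irr_body_size=0.90, irr_glide=1.05,
            dispersion=1.5,
        ),
        "chase_frames": ResponseSpec(
            baseline=1363.9, irr_status=1.44, irr_treatment=1.28,
            irr_interaction=0.71, irr_body_size=0.85, irr_glide=1.01,
            dispersion=2.0, zero_inflation=0.04,
        ),
    })
    # median latency to first sexual behavior (s) per cell; mixed-sex
    # males start sooner, most markedly with non-receptive females
    latency_median_s: dict = field(default_factory=lambda: {
        _cell_key("mixed_sex", "receptive"): 180.0,
        _cell_key("mixed_sex", "non_receptive"): 200.0,
        _cell_key("male_only", "receptive"): 300.0,
        _cell_key("male_only", "non_receptive"): 600.0,
    })
    glide_mean: dict = field(default_factory=lambda: {
        "receptive": 3.0, "non_receptive": 1.2,
    })
    body_size_diff_mean_cm: float = 1.2
    body_size_diff_sd_cm: float = 0.4
    random_effect_sds: dict = field(default_factory=lambda: {"batch": 0.10, "rearing_tank": 0.20})
    n_batches: int = 2
    males_per_tank: int = 3
    trial_duration_s: float = 900.0
    fps: float = 30.0

    @classmethod
    def null(cls, baseline: float = 15.91, dispersion: float = 3.0) -> "CountSimConfig":
        """All effects off: one NB response with no treatment/status/
        interaction/covariate effects and no random-effect variance.
        Used for type-I-error calibration of the count model."""
        cfg = cls()
        cfg.responses = {
            "displays": ResponseSpec(baseline=baseline, dispersion=dispersion),
            "sneaks": ResponseSpec(baseline=1.16, dispersion=1.5),
            "chase_frames": ResponseSpec(baseline=1363.9, dispersion=2.0),
        }
        cfg.random_effect_sds = {"batch": 0.0, "rearing_tank": 0.0}
        cfg.latency_median_s = {k: 300.0 for k in cfg.latency_median_s}
        cfg.glide_mean = {"receptive": 2.0, "non_receptive": 2.0}
        return cfg


def _draw_nb(rng: np.random.Generator, mu: np.ndarray, theta: float) -> np.ndarray:
    """NB2 draw via the gamma-Poisson mixture."""
    lam = rng.gamma(shape=theta, scale=np.asarray(mu) / theta)
    return rng.poisson(lam)


def simulate_counts(config: CountSimConfig | None = None, seed: int | tuple = 0) -> pd.DataFrame:
    """Simulate one no-choice behavior-count table.

    Returns a DataFrame in the BehaviorRecord CSV schema: one row per
    assay with columns ``male_id, treatment, female_status, displays,
    sneaks, total_behavior, association_s, chase_s, latency_s, censored,
    glide_count, body_size_diff_cm, batch, rearing_tank``.  Deterministic
    given ``seed``.
    """
    cfg = config if config is not None else CountSimConfig()
    rng = np.random.default_rng(seed)

    rows = []
    # random intercepts per response: batches shared study-wide, tanks
    # nested in treatment
    batches = [f"b{j + 1}" for j in range(cfg.n_batches)]
    re_batch = {
        resp: {b: rng.normal(0.0, cfg.random_effect_sds["batch"]) for b in batches}
        for resp in cfg.responses
    }
    re_tank: dict[str, dict[str, float]] = {resp: {} for resp in cfg.responses}

    idx = 0
    for cell, n_cell in cfg.n_per_cell.items():
        treatment, status = cell.split(":")
        for j in range(n_cell):
            idx += 1
            male_id = f"male{idx:03d}"
            batch = batches[idx % cfg.n_batches]
            tank = f"{treatment}_t{(idx // cfg.males_per_tank) + 1}"
            body = rng.normal(cfg.body_size_diff_mean_cm, cfg.body_size_diff_sd_cm)
            glides = int(rng.poisson(cfg.glide_mean[status]))

            counts = {}
            for resp, spec in cfg.responses.items():
                if tank not in re_tank[resp]:
                    re_tank[resp][tank] = rng.normal(
                        0.0, cfg.random_effect_sds["rearing_tank"]
                    )
                eta = (
                    math.log(spec.baseline)
                    + (status == "receptive") * math.log(spec.irr_status)
                    + (treatment == "mixed_sex") * math.log(spec.irr_treatment)
                    + (status == "receptive") * (treatment == "mixed_sex")
                    * math.log(spec.irr_interaction)
                    + body * math.log(spec.irr_body_size)
                    + glides * math.log(spec.irr_glide)
                    + re_batch[resp][batch]
                    + re_tank[resp][tank]
                )
                y = int(_draw_nb(rng, np.exp(eta), spec.dispersion))
                if spec.zero_inflation > 0 and rng.uniform() < spec.zero_inflation:
                    y = 0
                counts[resp] = y

            median = cfg.latency_median_s[cell]
            lat = rng.exponential(median / math.log(2.0))
            censored = lat >= cfg.trial_duration_s
            lat = min(lat, cfg.trial_duration_s)

            chase_s = counts["chase_frames"] / cfg.fps
            rows.append({
                "male_id": male_id,
                "treatment": treatment,
                "female_status": status,
                "displays": counts["displays"],
                "sneaks": counts["sneaks"],
                "total_behavior": counts["displays"] + counts["sneaks"],
                "association_s": float(np.clip(
                    rng.normal(250.0, 80.0), 0.0, cfg.trial_duration_s
                )),
                "chase_s": chase_s,
                "latency_s": float(lat),
                "censored": bool(censored),
                "glide_count": glides,
                "body_size_diff_cm": float(body),
                "batch": batch,
                "rearing_tank": tank,
            })
    return pd.DataFrame(rows)
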