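"""Association, chase and glide classifiers and bout merging."""

import numpy as np
import pytest

from courtrack import (
    EventInterval,
    SpeedBand,
    association_frames,
    detect_chase,
    detect_glides,
    merge_intervals,
)
from courtrack.errors import IntervalContractError, ParameterError
from courtrack.events import ClassifierThresholds, chase_mask, glide_mask
from courtrack import reference as ref

from conftest import build_trial

FPS = 30.0


def ev(start, end, kind="glide", actor="f", target="m"):
    return EventInterval(kind, actor, target, start, end, (end - start) / FPS)


class TestAssociation:
    def test_always_inside(self):
        n = 20
        trial = build_trial(np.zeros((n, 2)), np.tile([2.0, 0.0], (n, 1)))
        mask, total_s, count = association_frames(trial)
        assert count == n and total_s == pytest.approx(n / FPS)

    def test_boundary_is_strict(self):
        # exactly 4.0 cm is *not* association (strict <)
        n = 10
        trial = build_trial(np.zeros((n, 2)), np.tile([4.0, 0.0], (n, 1)))
        _, _, count = association_frames(trial)
        assert count == 0

    def test_missing_female_excluded(self):
        f = np.tile([1.0, 0.0], (10, 1))
        f[4] = np.nan
        trial = build_trial(np.zeros((10, 2)), f)
        mask, _, count = association_frames(trial)
        assert count == 9 and not mask[4]


def trailing_pair(n=30, step=0.2, trail=2.0):
    """Male following the female along +x, `trail` cm behind."""
    fx = np.arange(n) * step
    female = np.column_stack([fx, np.zeros(n)])
    male = np.column_stack([fx - trail, np.zeros(n)])
    return male, female


class TestChase:
    def test_trailing_male_yields_single_bout(self):
        male, female = trailing_pair()
        trial = build_trial(male, female)
        events = detect_chase(trial)
        # headings are defined up to the second-to-last frame
        assert [(e.start_frame, e.end_frame) for e in events] == [(0, 29)]
        assert events[0].duration_s == pytest.approx(29 / FPS)

    def test_leading_male_never_chases(self):
        male, female = trailing_pair(trail=-2.0)  # male in front
        trial = build_trial(male, female)
        assert detect_chase(trial) == []

    def test_antiparallel_headings_rejected(self):
        n = 30
        fx = np.arange(n) * 0.2
        female = np.column_stack([fx, np.zeros(n)])
        male = np.column_stack([fx[::-1] - 2.0, np.full(n, 0.5)])
        trial = build_trial(male, female)
        assert detect_chase(trial) == []

    def test_distance_strictly_below_3cm(self):
        male, female = trailing_pair(trail=3.0)
        trial = build_trial(male, female)
        assert not chase_mask(trial).any()

    def test_short_runs_suppressed(self):
        male, female = trailing_pair(n=30)
        male[4:] += 100.0  # only frames 0..3 qualify, run of 4 w/ headings
        trial = build_trial(male, female)
        thr = ClassifierThresholds(min_bout_frames=5)
        assert detect_chase(trial, thresholds=thr) == []


def radial_female(segments, start_cm=5.5):
    """Female on the +x axis, male at the origin: (n_frames, v) segments
    with v > 0 approaching the male, v < 0 retreating, in cm/s."""
    xs = [start_cm]
    for n, v in segments:
        for _ in range(n):
            xs.append(xs[-1] - v / FPS)
    xs = np.asarray(xs)
    female = np.column_stack([xs, np.zeros_like(xs)])
    male = np.zeros_like(female)
    return build_trial(male, female)


BAND = SpeedBand(2.0, 4.0)


class TestGlide:
    def test_single_approach_is_one_event(self):
        trial = radial_female([(30, 3.0)])
        events, count = detect_glides(trial, band=BAND)
        assert count == 1
        assert events[0].start_frame == 0

    def test_bouts_within_3s_merge(self):
        # two approaches separated by a 2.9 s retreat-and-return
        trial = radial_female(
            [(30, 3.0), (43, -10.0), (44, 10.0), (13, 3.0)], start_cm=5.5
        )
        _, count = detect_glides(trial, band=BAND)
        assert count == 1

    def test_bouts_beyond_3s_stay_separate(self):
        trial = radial_female(
            [(30, 3.0), (53, -10.0), (52, 10.0), (13, 3.0)], start_cm=5.5
        )
        _, count = detect_glides(trial, band=BAND)
        assert count == 2

    def test_fast_approach_outside_band_rejected(self):
        trial = radial_female([(10, 10.0)])
        mask, _ = glide_mask(trial, band=BAND)
        assert not mask.any()

    def test_oriented_away_rejected(self):
        trial = radial_female([(30, -3.0)], start_cm=1.0)  # retreating slowly
        mask, _ = glide_mask(trial, band=BAND)
        assert not mask.any()

    def test_beyond_60mm_rejected(self):
        trial = radial_female([(30, 3.0)], start_cm=20.0)
        mask, _ = glide_mask(trial, band=BAND)
        assert not mask.any()


class TestMergeIntervals:
    def test_all_gaps_within_window_collapse(self):
        evs = [ev(0, 10), ev(20, 30), ev(45, 60)]
        out = merge_intervals(evs, max_gap_s=3.0, fps=FPS)
        assert [(e.start_frame, e.end_frame) for e in out] == [(0, 60)]
        assert out[0].duration_s == pytest.approx(2.0)

    def test_zero_gap_window_is_identity(self):
        evs = [ev(0, 10), ev(20, 30)]
        assert merge_intervals(evs, 0.0, FPS) == evs

    def test_chain_merge_respects_each_gap(self):
        # gaps of 2 s and 4 s with a 3 s window -> two events
        evs = [ev(0, 30), ev(90, 120), ev(240, 270)]
        out = merge_intervals(evs, 3.0, FPS)
        assert [(e.start_frame, e.end_frame) for e in out] == [(0, 120), (240, 270)]

    def test_idempotent(self):
        evs = [ev(0, 30), ev(90, 120), ev(240, 270)]
        once = merge_intervals(evs, 3.0, FPS)
        assert merge_intervals(once, 3.0, FPS) == once

    def test_monotone_in_gap(self):
        rng = np.random.default_rng(0)
        starts = np.cumsum(rng.integers(5, 200, size=12))
        evs = [ev(int(s), int(s) + 4) for s in starts]
        counts = [
            len(merge_intervals(evs, g, FPS)) for g in (0.0, 0.5, 1.0, 3.0, 10.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_contract_violations_rejected(self):
        with pytest.raises(IntervalContractError):
            merge_intervals([ev(10, 20), ev(0, 5)], 1.0, FPS)
        with pytest.raises(IntervalContractError):
            merge_intervals([ev(0, 20), ev(10, 30)], 1.0, FPS)
        with pytest.raises(ParameterError):
            merge_intervals([ev(0, 10)], -1.0, FPS)


class TestClassifierProperties:
    def test_chase_frames_are_association_frames(self, clean_trial):
        # default radii nest: < 3 cm implies < 4 cm
        for fem in clean_trial.females:
            cm = chase_mask(clean_trial, fem)
            am, _, _ = association_frames(clean_trial, fem)
            assert not (cm & ~am).any()

    def test_rigid_motion_invariance(self, clean_trial):
        theta, tx, ty = 0.83, 5.0, -3.0
        rot = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        moved = clean_trial.copy()
        for t in moved.tracks:
            xy = np.column_stack([t.x, t.y]) @ rot.T + [tx, ty]
            t.x, t.y = xy[:, 0], xy[:, 1]
        for fem_before, fem_after in zip(clean_trial.females, moved.females):
            np.testing.assert_array_equal(
                chase_mask(clean_trial, fem_before), chase_mask(moved, fem_after)
            )
            np.testing.assert_array_equal(
                glide_mask(clean_trial, fem_before)[0],
                glide_mask(moved, fem_after)[0],
            )

    def test_vectorized_equals_frame_by_frame_loop(self, clean_trial):
        for fem in clean_trial.females:
            np.testing.assert_array_equal(
                chase_mask(clean_trial, fem),
                np.array(ref.chase_frames_reference(clean_trial, fem)),
            )
            np.testing.assert_array_equal(
                glide_mask(clean_trial, fem)[0],
                np.array(ref.glide_frames_reference(clean_trial, fem)),
            )
            np.testing.assert_array_equal(
                association_frames(clean_trial, fem)[0],
                np.array(ref.association_frames_reference(clean_trial, fem)),
            )


def test_threshold_validation_warns_on_inverted_radii():
    with pytest.warns(UserWarning, match="chase_distance_cm"):
        ClassifierThresholds(chase_distance_cm=5.0)
    with pytest.raises(ParameterError):
        ClassifierThresholds(min_bout_frames=0)
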