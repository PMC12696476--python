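"""Reading, calibration, gap handling and the tracking-quality filter."""

import numpy as np
import pandas as pd
import pytest

from courtrack import (
    CalibrationSpec,
    Track,
    Trial,
    filter_by_quality,
    interpolate_gaps,
    read_trajectories,
    tracked_fraction,
)
from courtrack.errors import (
    EmptyTrialError,
    FormatError,
    ParameterError,
    RoleError,
)
from courtrack.traj_io import write_trajectories


def write_csv(path, rows, cols=("frame", "id", "x", "y")):
    pd.DataFrame(rows, columns=list(cols)).to_csv(path, index=False)
    return path


CAL = CalibrationSpec(px_per_cm=2.0)
ROLES = {"1": "male"}


class TestRead:
    def test_dense_identity(self, tmp_path):
        p = write_csv(tmp_path / "t.csv", [(0, 1, 0, 0), (1, 1, 2, 2), (2, 1, 4, 4)])
        trial = read_trajectories(p, CAL, ROLES, design=None)
        t = trial.tracks[0]
        assert t.n_frames == 3
        assert not t.missing.any()

    def test_absent_frame_flagged_missing(self, tmp_path):
        p = write_csv(tmp_path / "t.csv", [(0, 1, 0, 0), (2, 1, 4, 4)])
        t = read_trajectories(p, CAL, ROLES, design=None).tracks[0]
        assert t.n_frames == 3
        assert list(t.missing) == [False, True, False]
        assert list(t.tracked) == [True, False, True]

    def test_pixel_to_cm_calibration(self, tmp_path):
        # px / px_per_cm: (10, 4) px at 2 px/cm -> (5, 2) cm
        p = write_csv(tmp_path / "t.csv", [(0, 1, 10, 4), (1, 1, 6, 0)])
        t = read_trajectories(p, CAL, ROLES, design=None).tracks[0]
        assert t.x[0] == 5.0 and t.y[0] == 2.0
        assert t.x[1] == 3.0 and t.y[1] == 0.0

    def test_duplicate_rows_rejected(self, tmp_path):
        p = write_csv(tmp_path / "t.csv", [(0, 1, 0, 0), (0, 1, 1, 1)])
        with pytest.raises(FormatError, match="duplicate"):
            read_trajectories(p, CAL, ROLES, design=None)

    def test_unknown_individual_rejected(self, tmp_path):
        p = write_csv(tmp_path / "t.csv", [(0, 1, 0, 0), (0, 2, 1, 1)])
        with pytest.raises(RoleError, match="not present in roles"):
            read_trajectories(p, CAL, ROLES, design=None)

    def test_roundtrip_preserves_coordinates(self, tmp_path):
        rng = np.random.default_rng(3)
        rows = [(f, 1, rng.uniform(0, 40), rng.uniform(0, 40)) for f in range(50)]
        p = write_csv(tmp_path / "t.csv", rows)
        trial = read_trajectories(p, CAL, ROLES, design=None)
        write_trajectories(trial, tmp_path / "back.csv")
        again = read_trajectories(tmp_path / "back.csv", CAL, ROLES, design=None)
        np.testing.assert_allclose(again.tracks[0].x, trial.tracks[0].x)
        np.testing.assert_allclose(again.tracks[0].y, trial.tracks[0].y)


def make_gappy_trial(missing_frames, n=10, fps=30.0):
    x = np.arange(n, dtype=float)
    y = np.arange(n, dtype=float)
    x[list(missing_frames)] = np.nan
    y[list(missing_frames)] = np.nan
    tr = Track("m", "male", x, y)
    f = Track("f", "female", np.zeros(n) + 20, np.zeros(n))
    return Trial("g", "no_choice", [tr, f], CalibrationSpec(fps=fps))


class TestInterpolation:
    def test_single_frame_gap_filled_linearly(self):
        trial = make_gappy_trial([1])
        out = interpolate_gaps(trial, max_gap_s=1.0)
        t = out.tracks[0]
        assert t.x[1] == 1.0 and t.y[1] == 1.0
        assert t.interpolated[1] and not t.tracked[1]

    def test_long_gap_untouched(self):
        trial = make_gappy_trial(range(1, 9))  # 8-frame gap at 30 fps
        out = interpolate_gaps(trial, max_gap_s=0.1)  # allows 3 frames
        assert np.isnan(out.tracks[0].x[1:9]).all()

    def test_zero_max_gap_is_identity(self):
        trial = make_gappy_trial([1])
        out = interpolate_gaps(trial, max_gap_s=0.0)
        assert np.isnan(out.tracks[0].x[1])
        assert not out.tracks[0].interpolated.any()

    def test_leading_trailing_gaps_stay_missing(self):
        trial = make_gappy_trial([0, 9])
        out = interpolate_gaps(trial, max_gap_s=5.0)
        assert np.isnan(out.tracks[0].x[0]) and np.isnan(out.tracks[0].x[9])

    def test_negative_gap_rejected(self):
        with pytest.raises(ParameterError):
            interpolate_gaps(make_gappy_trial([]), max_gap_s=-1)


def trial_with_fraction(n_tracked, n=100):
    x = np.zeros(n)
    x[n_tracked:] = np.nan
    m = Track("m", "male", x, x.copy())
    f = Track("f", "female", np.zeros(n), np.zeros(n))
    return Trial("q", "no_choice", [m, f], CalibrationSpec())


class TestQualityFilter:
    def test_fully_tracked_passes(self):
        rep = tracked_fraction(trial_with_fraction(100))
        assert rep.trial_fraction == 1.0 and rep.passed

    def test_79_of_100_rejected(self):
        rep = tracked_fraction(trial_with_fraction(79))
        assert rep.trial_fraction == pytest.approx(0.79)
        assert not rep.passed

    def test_80_of_100_retained(self):
        # the filter discards strictly below 80%; exactly 80% stays
        rep = tracked_fraction(trial_with_fraction(80))
        assert rep.trial_fraction == pytest.approx(0.80)
        assert rep.passed

    def test_minimum_across_individuals(self):
        rep = tracked_fraction(trial_with_fraction(50))
        assert rep.tracked_fraction["m"] == 0.5
        assert rep.tracked_fraction["f"] == 1.0
        assert rep.trial_fraction == 0.5

    def test_interpolation_does_not_change_quality(self):
        trial = make_gappy_trial([3, 4])
        before = tracked_fraction(trial).trial_fraction
        after = tracked_fraction(interpolate_gaps(trial, max_gap_s=1.0)).trial_fraction
        assert before == after

    def test_batch_filter_keeps_only_passing(self):
        trials = [trial_with_fraction(k) for k in (100, 85, 80, 79, 10)]
        kept, reports = filter_by_quality(trials)
        assert [t.trial_id for t in kept] == ["q", "q", "q"]
        assert len(reports) == 5
        assert sum(r.passed for r in reports) == 3

    def test_zero_frame_trial_rejected(self):
        m = Track("m", "male", np.array([]), np.array([]))
        f = Track("f", "female", np.array([]), np.array([]))
        trial = Trial("e", "no_choice", [m, f], CalibrationSpec())
        with pytest.raises(EmptyTrialError):
            tracked_fraction(trial)


class TestTrialInvariants:
    def test_exactly_one_male_required(self):
        f = Track("f", "female", np.zeros(3), np.zeros(3))
        with pytest.raises(RoleError):
            Trial("t", "no_choice", [f], CalibrationSpec())

    def test_dichotomous_needs_distinct_receptivity(self):
        m = Track("m", "male", np.zeros(3), np.zeros(3))
        f1 = Track("f1", "female_receptive", np.zeros(3), np.zeros(3))
        f2 = Track("f2", "female_receptive", np.zeros(3), np.zeros(3))
        with pytest.raises(RoleError):
            Trial("t", "dichotomous", [m, f1, f2], CalibrationSpec())
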