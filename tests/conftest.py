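import numpy as np
import pytest

from courtrack import (
    CalibrationSpec,
    Track,
    Trial,
    make_standard_script,
    simulate_trial,
)


@pytest.fixture(scope="session")
def calibration():
    return CalibrationSpec()


def build_trial(
    male_xy,
    female_xy,
    fps=30.0,
    female_role="female",
    extra_tracks=(),
    design="no_choice",
):
    """Trial from explicit (n, 2) position arrays (cm, arena-centred)."""
    male_xy = np.asarray(male_xy, dtype=float)
    female_xy = np.asarray(female_xy, dtype=float)
    tracks = [
        Track("m", "male", male_xy[:, 0], male_xy[:, 1]),
        Track("f", female_role, female_xy[:, 0], female_xy[:, 1]),
    ]
    tracks += list(extra_tracks)
    return Trial(
        trial_id="built",
        design=design,
        tracks=tracks,
        calibration=CalibrationSpec(fps=fps),
    )


@pytest.fixture(scope="session")
def clean_dichotomous():
    """One zero-noise scripted dichotomous trial plus its ground truth."""
    script = make_standard_script("dichotomous", duration_s=120.0)
    return simulate_trial(script, seed=11, trial_id="clean")


@pytest.fixture(scope="session")
def clean_trial(clean_dichotomous):
    return clean_dichotomous[0]
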