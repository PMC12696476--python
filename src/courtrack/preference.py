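"""Trial-level response variables for mate-choice analysis.

From classifier output and human-scored behavior counts this module
derives the quantities the downstream models consume: the preference
ratio of a dichotomous trial, censored latency to first sexual
behavior, per-male glide-count differences (the receptivity-validation
statistic), and the rank agreement between behavioral and
proximity-based preference measures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .errors import CourtrackError, InsufficientDataError, ParameterError

MIXED_SEX = "mixed_sex"
MALE_ONLY = "male_only"
RECEPTIVE = "receptive"
NON_RECEPTIVE = "non_receptive"

DEFAULT_TRIAL_DURATION_S = 900.0


@dataclass
class BehaviorRecord:
    """One no-choice assay's responses and covariates.

    ``displays`` and ``sneaks`` are human-scored counts of sigmoid
    displays and sneak (gonopodial-thrust) attempts;
    ``total_behavior`` is their sum.  ``association_s`` and ``chase_s``
    come from the trajectory classifiers.  ``latency_s`` is the time to
    the first sexual behavior of either kind, censored at the trial
    duration (``censored=True`` means none occurred).
    ``body_size_diff_cm`` is female minus male body length;
    ``glide_count`` is the female's merged glide-approach count.
    """

    male_id: str
    treatment: str
    female_status: str
    displays: int
    sneaks: int
    association_s: float
    chase_s: float
    latency_s: float
    censored: bool
    glide_count: int
    body_size_diff_cm: float
    batch: str = ""
    rearing_tank: str = ""
    total_behavior: int = field(init=False)

    def __post_init__(self) -> None:
        if self.treatment not in (MIXED_SEX, MALE_ONLY):
            raise ParameterError(f"unknown treatment {self.treatment!r}")
        if self.female_status not in (RECEPTIVE, NON_RECEPTIVE):
            raise ParameterError(f"unknown female_status {self.female_status!r}")
        for name in ("displays", "sneaks", "glide_count"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.latency_s < 0:
            raise ParameterError("latency_s must be >= 0")
        self.total_behavior = self.displays + self.sneaks


@dataclass(frozen=True)
class PreferenceScore:
    """Association-time preference of one dichotomous trial.

    ``ratio`` is (time with receptive - time with non-receptive) /
    (total time with both), in [-1, 1]; None (flagged) when the male
    associated with neither female.
    """

    trial_id: str
    time_receptive_s: float
    time_nonreceptive_s: float
    ratio: float | None

    @property
    def defined(self) -> bool:
        return self.ratio is not None


def preference_ratio(time_receptive_s: float, time_nonreceptive_s: float) -> float:
    """Preference ratio (tR - tN) / (tR + tN) for the receptive female.

    +1: all association time with the receptive female; -1: all with the
    non-receptive one; 0: equal times.  Raises when both times are zero
    (callers record the trial as missing).
    """
    tR, tN = float(time_receptive_s), float(time_nonreceptive_s)
    if tR < 0 or tN < 0:
        raise ParameterError("association times must be >= 0")
    if tR + tN == 0:
        raise CourtrackError("preference ratio undefined: zero total association time")
    return (tR - tN) / (tR + tN)


def score_preference(
    trial_id: str, time_receptive_s: float, time_nonreceptive_s: float
) -> PreferenceScore:
    """Build a :class:`PreferenceScore`, flagging the undefined case
    (zero total association time) instead of raising."""
    try:
        ratio = preference_ratio(time_receptive_s, time_nonreceptive_s)
    except CourtrackError:
        ratio = None
    return PreferenceScore(
        trial_id=trial_id,
        time_receptive_s=time_receptive_s,
        time_nonreceptive_s=time_nonreceptive_s,
        ratio=ratio,
    )


def latency_first_behavior(
    timestamps_s: Iterable[float],
    trial_duration_s: float = DEFAULT_TRIAL_DURATION_S,
) -> tuple[float, bool]:
    """Latency to the first sexual behavior of any kind.

    ``timestamps_s`` pools the onset times of all scored behaviors
    (displays and sneak attempts).  Returns ``(latency_s, censored)``;
    with no behavior the latency is right-censored at the trial
    duration.
    """
    ts = sorted(float(t) for t in timestamps_s)
    if ts and ts[-1] > trial_duration_s:
        raise ParameterError(
            f"behavior timestamp {ts[-1]} exceeds trial duration {trial_duration_s}"
        )
    if ts and ts[0] < 0:
        raise ParameterError(f"negative behavior timestamp {ts[0]}")
    if not ts:
        return trial_duration_s, True
    return ts[0], False


def glide_difference(glides_receptive: int, glides_nonreceptive: int) -> int:
    """Per-male glide-count difference (receptive minus non-receptive
    female) from one dichotomous trial; positive values indicate the
    receptive female approached more."""
    return int(glides_receptive) - int(glides_nonreceptive)


@dataclass(frozen=True)
class TTestResult:
    mean: float
    ci_low: float
    ci_high: float
    t: float
    df: int
    p: float
    degenerate: bool = False


def glide_validation_test(differences: Sequence[float]) -> TTestResult:
    """One-sample two-sided t-test of the per-male glide differences
    against zero, with a 95% CI of the mean — the receptivity-category
    validation check.  Zero-variance input is flagged degenerate."""
    d = np.asarray(list(differences), dtype=float)
    d = d[~np.isnan(d)]
    if d.size < 2:
        raise InsufficientDataError("need >= 2 finite glide differences")
    mean = float(np.mean(d))
    df = int(d.size - 1)
    if np.allclose(d, d[0]):
        return TTestResult(mean=mean, ci_low=mean, ci_high=mean, t=math.nan,
                           df=df, p=math.nan, degenerate=True)
    res = stats.ttest_1samp(d, 0.0)
    ci = res.confidence_interval(0.95)
    return TTestResult(
        mean=mean,
        ci_low=float(ci.low),
        ci_high=float(ci.high),
        t=float(res.statistic),
        df=df,
        p=float(res.pvalue),
        degenerate=False,
    )


def behavior_proximity_agreement(
    records: Sequence[BehaviorRecord],
    n_permutations: int = 5000,
    seed: int | None = 0,
) -> tuple[float, float]:
    """Spearman rank correlation between behavioral preference
    (``total_behavior``) and proximity preference (``association_s``).

    Checks that human-scored behavior counts and the 4-cm association
    classifier rank males concordantly.  Ties are midranked.  Returns
    ``(rho, p)`` with a permutation p-value (two-sided, shuffling one
    variable, ``n_permutations`` draws seeded by ``seed``).
    """
    if len(records) < 5:
        raise InsufficientDataError("need >= 5 paired records")
    x = np.array([r.total_behavior for r in records], dtype=float)
    y = np.array([r.association_s for r in records], dtype=float)
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise InsufficientDataError("zero variance in one variable; rho undefined")
    rho = float(stats.spearmanr(x, y).statistic)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(y)
        r = stats.spearmanr(x, perm).statistic
        if abs(r) >= abs(rho) - 1e-12:
            count += 1
    p = (count + 1) / (n_permutations + 1)
    return rho, float(p)
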