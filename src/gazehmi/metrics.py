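"""Per-trial derived quantities: signed endpoint angles, the curvature
index, learning-phase assignment, and the per-trial decoding outcome table.

Sign conventions (documented once, used everywhere):

* target-relative *angles* are clockwise-positive arc deg in ``(-180, 180]``,
  so an end point on the optimal aim point (one distortion counterclockwise
  of the intended object) has angle -45 to the intended object and 0 to the
  optimal point;
* the *curvature index* is counterclockwise-positive: a trajectory deviating
  counterclockwise (to the left of the chord, seen along the movement) from
  the straight start-to-end line has positive signed area.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DegenerateTrajectoryError, UndefinedAngleError
from .geometry import clock_angle, wrap_angle

__all__ = [
    "AngleMetrics",
    "CurvatureIndex",
    "SessionLayout",
    "PHASES",
    "signed_angle",
    "angle_metrics",
    "curvature_index",
    "assign_phase",
    "decoding_outcome_table",
]

PHASES = ("pre", "early", "mid", "late", "post")


@dataclass(frozen=True)
class AngleMetrics:
    """Signed angles of one end point relative to the intended object and to
    the optimal aim point (clockwise-positive arc deg)."""

    angle_to_intended: float
    angle_to_optimal: float
    optimal_clock_angle: float


@dataclass(frozen=True)
class CurvatureIndex:
    """Signed area under the rotated, time-normalised saccade trajectory
    (deg x normalised time); counterclockwise deviation positive."""

    value: float
    n_steps: int = 24


@dataclass(frozen=True)
class SessionLayout:
    """Trial counts of one recording session: circle-off baseline, feedback
    (learning) block, circle-off aftereffect block."""

    n_pre: int = 20
    n_feedback: int = 200
    n_post: int = 20
    phase_window: int = 20  # early/late window length within the feedback block

    def __post_init__(self):
        if min(self.n_pre, self.n_feedback, self.n_post) <= 0:
            raise ValueError("trial counts must be positive")
        if self.phase_window * 2 > self.n_feedback:
            raise ValueError("early/late windows overlap")

    @property
    def n_trials(self) -> int:
        return self.n_pre + self.n_feedback + self.n_post


def signed_angle(endpoint, reference_clock_angle) -> float:
    """Clockwise-positive angle (arc deg) of an end point relative to a
    reference clock angle, wrapped into ``(-180, 180]``."""
    x = np.asarray(endpoint[0], dtype=float)
    y = np.asarray(endpoint[1], dtype=float)
    if np.any(np.hypot(x, y) == 0.0):
        raise UndefinedAngleError("angle undefined at the fixation cross")
    out = wrap_angle(clock_angle(x, y) - np.asarray(reference_clock_angle))
    return float(out) if out.ndim == 0 else out


def angle_metrics(endpoint, intended_clock_angle: float,
                  distortion: float = 45.0) -> AngleMetrics:
    """Angles of one end point to the intended object and the optimal point.

    The optimal point sits ``distortion`` arc deg counterclockwise of the
    intended object, hence ``angle_to_optimal = angle_to_intended +
    distortion`` (wrapped).
    """
    a_int = signed_angle(endpoint, intended_clock_angle)
    optimal = (intended_clock_angle - distortion) % 360.0
    return AngleMetrics(
        angle_to_intended=a_int,
        angle_to_optimal=float(wrap_angle(a_int + distortion)),
        optimal_clock_angle=optimal,
    )


def curvature_index(trajectory, n_steps: int = 24) -> CurvatureIndex:
    """Signed-area curvature of a saccade trajectory.

    The trajectory is translated so its start is at the origin, rotated so the
    end point lies on the +x axis (a canonical rightward saccade; leftward/
    counterclockwise deviation maps to +y), linearly resampled to ``n_steps``
    time steps, and the trapezoidal integral of the perpendicular deviation
    over normalised time in [0, 1] is returned.
    """
    pts = np.asarray(trajectory, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise DegenerateTrajectoryError("need >= 2 screen points")
    rel = pts - pts[0]
    dx, dy = rel[-1]
    chord = np.hypot(dx, dy)
    if chord == 0.0:
        raise DegenerateTrajectoryError("start and end point coincide")
    c, s = dx / chord, dy / chord
    y_rot = -s * rel[:, 0] + c * rel[:, 1]
    s_orig = np.linspace(0.0, 1.0, pts.shape[0])
    s_new = np.linspace(0.0, 1.0, n_steps)
    y_resampled = np.interp(s_new, s_orig, y_rot)
    value = float(np.trapezoid(y_resampled, s_new))
    return CurvatureIndex(value=value, n_steps=n_steps)


def assign_phase(trial_index: int, layout: SessionLayout = SessionLayout(),
                 ) -> str:
    """Learning phase of a 1-based trial index within a session.

    pre = the baseline circle-off block; early/late = the first/last
    ``phase_window`` feedback trials; mid = feedback trials in between;
    post = the final circle-off block.
    """
    if not 1 <= trial_index <= layout.n_trials:
        raise ValueError(f"trial index {trial_index} outside session "
                         f"(1..{layout.n_trials})")
    if trial_index <= layout.n_pre:
        return "pre"
    fb = trial_index - layout.n_pre  # 1-based feedback trial number
    if fb <= layout.n_feedback:
        if fb <= layout.phase_window:
            return "early"
        if fb > layout.n_feedback - layout.phase_window:
            return "late"
        return "mid"
    return "post"


def decoding_outcome_table(trials: pd.DataFrame,
                           layout: SessionLayout = SessionLayout(),
                           ) -> pd.DataFrame:
    """Tidy per-trial valid-decoding table for learning-trend analyses.

    Expects feedback trials carrying ``participant``, ``session``,
    ``condition`` (motor/action), ``order``, ``trial`` (1-based within
    session) and ``decoding_error`` columns.  Emits one row per feedback
    trial with the binary outcome (1 = valid decoding, too-far counts as 0)
    and the feedback-trial number centred on the middle of the learning
    block, so a trend model's intercept refers to mid-learning performance.
    """
    fb = trials[(trials["trial"] > layout.n_pre)
                & (trials["trial"] <= layout.n_pre + layout.n_feedback)]
    learning_trial = fb["trial"] - layout.n_pre
    outcome = ((~fb["too_far"].astype(bool))
               & (~fb["decoding_error"].fillna(True).astype(bool))).astype(int)
    out = pd.DataFrame({
        "participant": fb["participant"].values,
        "session": fb["session"].values,
        "condition": fb["condition"].values,
        "order": fb["order"].values,
        "learning_trial": learning_trial.values,
        "trial_centered": (learning_trial - layout.n_feedback // 2).values,
        "outcome": outcome.values,
    })
    return out.reset_index(drop=True)
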