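"""Synthetic gaze data with the statistical structure the analysis assumes.

The generator emulates one participant interacting with the simulated
gaze-controlled interface: each trial has a fixation period, a primary
saccade toward the participant's current aim point, and usually a secondary
corrective saccade toward the current oculomotor goal.  Saccade kinematics
follow a minimum-jerk velocity profile with a main-sequence duration law
(duration_ms = 2.2 * amplitude_deg + 21 by default -- standard textbook
values, not measurements from any particular dataset).  Streams are sampled
at 1000 Hz.

Two learner models adjust the aim direction across feedback trials:

* ``error_based`` (motor feedback): the signed angle of the feedback dot
  relative to the intended object is reduced proportionally
  (``aim <- aim - eta * error``), yielding geometric convergence of the aim
  toward the optimal point;
* ``reward_based`` (action feedback): win-stay/lose-shift -- on a decoding
  error the aim takes a random exploration step, on success it is kept and
  the exploration spread shrinks.

Both learners can start updating only after a per-participant onset delay
(trials spent aiming at the intended object before the contingency is
discovered), which staggers convergence times across a cohort and produces
the bimodal pooled distribution of endpoint angles during first-session
learning.  A second session starts at baseline but retrieves a fraction
(``savings``) of the previously learned aim offset once feedback resumes,
with a proportionally raised learning rate, reproducing savings.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .events import DetectionSettings, GazeStream, detect_offset_online, \
    detect_onset_online
from .geometry import (SceneGeometry, ScreenPoint, apply_distortion,
                       decode_object, evaluate_trial, from_clock,
                       render_feedback, wrap_angle)
from .metrics import SessionLayout, assign_phase, signed_angle

__all__ = [
    "KinematicParams",
    "LearnerState",
    "SessionLayout",
    "generate_saccade",
    "learner_update",
    "simulate_session",
    "simulate_experiment",
]


@dataclass(frozen=True)
class KinematicParams:
    """Saccade kinematics, noise, and trial timing of the generator.

    Main-sequence and minimum-jerk defaults are generic oculomotor values;
    all noise magnitudes are configuration, not measurements.
    """

    main_sequence_slope: float = 2.2        # ms per deg
    main_sequence_intercept: float = 21.0   # ms
    endpoint_noise_sd: float = 0.5          # deg, isotropic motor noise
    aim_noise_sd: float = 5.0               # arc deg, angular aim noise
    bow_coefficient: float = 0.0            # deg, ccw-positive trajectory bow
    sampling_rate: float = 1000.0           # Hz
    latency_median_ms: float = 350.0        # lognormal median
    latency_log_sd: float = 0.3
    early_latency_increment_ms: float = 80.0  # added during early learning
    fixation_duration_range: Tuple[float, float] = (500.0, 1000.0)
    p_secondary: float = 0.9
    secondary_latency_range: Tuple[float, float] = (150.0, 350.0)
    secondary_noise_sd: float = 0.3         # deg

    def duration_ms(self, amplitude: float) -> float:
        return self.main_sequence_slope * amplitude + self.main_sequence_intercept


@dataclass(frozen=True)
class LearnerState:
    """Aim state and learning parameters of one simulated participant.

    ``aim_offset`` is the clockwise-positive angular offset (arc deg) of the
    aim direction relative to the intended object; 0 aims at the object,
    -45 at the optimal point that cancels the interface's distortion.
    """

    mode: str = "error_based"               # or "reward_based"
    aim_offset: float = 0.0                 # arc deg in (-180, 180]
    learning_rate: float = 0.15             # eta in [0, 1]
    explore_sd: float = 15.0                # arc deg, reward-mode step SD
    explore_decay: float = 0.95             # shrink factor on success
    onset_delay: int = 0                    # feedback trials before learning
    feedback_trials_seen: int = 0
    memory: float = 0.0                     # stored offset for savings
    retrieval_offset: Optional[float] = None  # applied at first feedback trial

    def __post_init__(self):
        if self.mode not in ("error_based", "reward_based"):
            raise ConfigurationError(f"unknown learner mode {self.mode!r}")
        if not 0.0 <= self.learning_rate <= 1.0:
            raise ConfigurationError("learning_rate must lie in [0, 1]")


def learner_update(state: LearnerState, feedback_angle_to_intended: float,
                   success: bool, rng: np.random.Generator) -> LearnerState:
    """One learning step from a feedback trial's outcome.

    ``feedback_angle_to_intended`` is the signed (clockwise-positive) angle
    of the feedback signal -- the distorted end point -- relative to the
    intended object; the error-based learner subtracts ``eta`` times it.
    The reward-based learner takes a random exploration step after an error
    and keeps (win-stay) its aim after a success, shrinking the exploration
    spread.  Updates begin only after ``onset_delay`` feedback trials.
    """
    seen = state.feedback_trials_seen + 1
    if state.feedback_trials_seen < state.onset_delay:
        return replace(state, feedback_trials_seen=seen)
    if state.mode == "error_based":
        new_aim = wrap_angle(state.aim_offset
                             - state.learning_rate * feedback_angle_to_intended)
        return replace(state, aim_offset=float(new_aim),
                       feedback_trials_seen=seen)
    if success:
        return replace(state, explore_sd=state.explore_sd * state.explore_decay,
                       feedback_trials_seen=seen)
    step = rng.normal(0.0, state.explore_sd)
    return replace(state, aim_offset=float(wrap_angle(state.aim_offset + step)),
                   feedback_trials_seen=seen)


def _min_jerk_s(tau: np.ndarray) -> np.ndarray:
    return tau ** 3 * (10.0 - 15.0 * tau + 6.0 * tau ** 2)


def generate_saccade(start, aim_point, params: KinematicParams,
                     rng: np.random.Generator, t0: float = 0.0):
    """One saccade segment sampled at 1 ms with its kinematic ground truth.

    The planned amplitude (start to aim point) sets the duration via the
    main sequence; the landing point is the aim point plus isotropic motor
    noise; the trajectory is a minimum-jerk motion along the start->landing
    chord plus an optional perpendicular sinusoidal bow whose coefficient is
    the peak deviation in deg (counterclockwise positive), giving an
    expected curvature index of ``2 c / pi``.

    Returns ``(t, x, y, truth)`` where ``truth`` holds onset/offset times,
    the landing point, amplitude, and duration.
    """
    sx, sy = float(start[0]), float(start[1])
    ax, ay = float(aim_point[0]), float(aim_point[1])
    planned = math.hypot(ax - sx, ay - sy)
    if planned <= 0.0:
        raise ValueError("aim point must differ from start")
    duration = params.duration_ms(planned)
    n = max(int(round(duration)), 4)
    lx = ax + rng.normal(0.0, params.endpoint_noise_sd)
    ly = ay + rng.normal(0.0, params.endpoint_noise_sd)
    dx, dy = lx - sx, ly - sy
    chord = math.hypot(dx, dy)
    tau = np.arange(n + 1) / n
    s = _min_jerk_s(tau)
    x = sx + s * dx
    y = sy + s * dy
    if params.bow_coefficient != 0.0 and chord > 0.0:
        px, py = -dy / chord, dx / chord  # left of motion = ccw-positive
        bow = params.bow_coefficient * np.sin(np.pi * tau)
        x = x + bow * px
        y = y + bow * py
    t = t0 + np.arange(n + 1, dtype=float)
    truth = {
        "onset_t": t0,
        "offset_t": t0 + n,
        "landing": ScreenPoint(lx, ly),
        "amplitude": chord,
        "duration": float(n),
    }
    return t, x, y, truth


def _assemble_stream(pre_samples: int, fixation_off_t: float,
                     primary, secondary, trial_id: int) -> GazeStream:
    """Concatenate fixation, primary and (optional) secondary segments into
    one 1 kHz trial stream; sample index equals time in ms."""
    tp, xp, yp, truth_p = primary
    pieces_x = [np.zeros(pre_samples)]
    pieces_y = [np.zeros(pre_samples)]
    pieces_x.append(xp)
    pieces_y.append(yp)
    land = truth_p["landing"]
    if secondary is not None:
        ts, xs, ys, truth_s, sec_latency = secondary
        hold = int(round(sec_latency)) - 1  # secondary onset lands on its t0
        pieces_x.append(np.full(hold, land.x))
        pieces_y.append(np.full(hold, land.y))
        pieces_x.append(xs)
        pieces_y.append(ys)
        end = truth_s["landing"]
        pieces_x.append(np.full(200, end.x))
        pieces_y.append(np.full(200, end.y))
    else:
        pieces_x.append(np.full(400, land.x))
        pieces_y.append(np.full(400, land.y))
    x = np.concatenate(pieces_x)
    y = np.concatenate(pieces_y)
    t = np.arange(x.size, dtype=float)
    return GazeStream(t=t, x=x, y=y, fixation_off_t=fixation_off_t,
                      trial_id=trial_id)


_TRIAL_COLUMNS = [
    "participant", "session", "condition", "order", "trial", "phase",
    "intended_object", "intended_clock", "aim_offset", "latency_ms",
    "endpoint_x", "endpoint_y", "amplitude", "duration_ms",
    "distorted_x", "distorted_y", "decoded_object", "too_far",
    "decoding_error", "outcome", "angle_to_intended", "angle_to_optimal",
    "sec_present", "sec_latency_ms", "sec_endpoint_x", "sec_endpoint_y",
    "sec_amplitude", "feedback_kind", "feedback_x", "feedback_y",
    "colored_object", "truth_onset_t", "truth_offset_t",
]


def simulate_session(layout: SessionLayout, learner: LearnerState,
                     kinematics: KinematicParams, scene: SceneGeometry,
                     rng: np.random.Generator, condition: str = "motor",
                     participant: int = 0, session: int = 1,
                     order: str = "motor_first",
                     preference: Optional[np.ndarray] = None,
                     stream_mode: str = "none",
                     detection: DetectionSettings = DetectionSettings()):
    """Simulate one recording session (circle-off, feedback, circle-off).

    Feedback trials run the full interface loop -- distortion, decoding,
    feedback rendering, learner update; circle-off trials skip all three.
    The intended object is drawn uniformly unless a per-participant
    ``preference`` probability vector is given.

    ``stream_mode='none'`` returns the trial table with exact kinematic
    ground truth only (fast, used for cohort-scale studies);
    ``stream_mode='full'`` additionally produces 1 kHz gaze streams per
    trial, with the feedback onset determined by the online detector plus
    the configured detection-to-display delay.

    Returns ``(trials, streams, final_learner)``; ``streams`` is ``None``
    in ``'none'`` mode.
    """
    if condition not in ("motor", "action"):
        raise ConfigurationError(f"unknown feedback condition {condition!r}")
    if stream_mode not in ("none", "full"):
        raise ConfigurationError("stream_mode must be 'none' or 'full'")
    n = layout.n_trials
    lo_f, hi_f = kinematics.fixation_duration_range
    fix_durs = rng.uniform(lo_f, hi_f, n)
    lat_raw = rng.lognormal(np.log(kinematics.latency_median_ms),
                            kinematics.latency_log_sd, n)
    aim_noise = rng.normal(0.0, kinematics.aim_noise_sd, n)
    if preference is None:
        intended_all = rng.integers(0, scene.n_objects, n)
    else:
        p = np.asarray(preference, dtype=float)
        intended_all = rng.choice(scene.n_objects, size=n, p=p / p.sum())
    sec_flags = rng.random(n) < kinematics.p_secondary
    lo_s, hi_s = kinematics.secondary_latency_range
    sec_lats = rng.uniform(lo_s, hi_s, n)
    fast = stream_mode == "none"
    if fast:
        end_noise = rng.normal(0.0, kinematics.endpoint_noise_sd, (n, 2))
        sec_noise = rng.normal(0.0, kinematics.secondary_noise_sd, (n, 2))

    rows: List[dict] = []
    streams: Optional[List[GazeStream]] = None if fast else []
    state = learner
    for i in range(n):
        trial = i + 1
        phase = assign_phase(trial, layout)
        is_feedback = phase in ("early", "mid", "late")
        if is_feedback and state.retrieval_offset is not None:
            state = replace(state, aim_offset=float(state.retrieval_offset),
                            retrieval_offset=None)
        intended = int(intended_all[i])
        intended_clock = float(scene.object_clock_angles[intended])
        latency = float(lat_raw[i])
        if phase == "early":
            latency += kinematics.early_latency_increment_ms
        aim_clock = intended_clock + state.aim_offset + float(aim_noise[i])
        ax, ay = from_clock(aim_clock, scene.object_radius)
        fix_dur = float(fix_durs[i])

        if fast:
            ex = float(ax + end_noise[i, 0])
            ey = float(ay + end_noise[i, 1])
            amplitude = math.hypot(ex, ey)
            duration = float(max(int(round(kinematics.duration_ms(
                scene.object_radius))), 4))
            onset_t = fix_dur + latency
            offset_t = onset_t + duration
        else:
            fix_i, lat_i = int(round(fix_dur)), int(round(latency))
            latency = float(lat_i)
            onset_t = float(fix_i + lat_i)
            tpr, xpr, ypr, truth = generate_saccade(
                (0.0, 0.0), (ax, ay), kinematics, rng, t0=onset_t)
            ex, ey = truth["landing"]
            amplitude = truth["amplitude"]
            duration = truth["duration"]
            offset_t = truth["offset_t"]

        angle_int = signed_angle((ex, ey), intended_clock)
        angle_opt = float(wrap_angle(angle_int + scene.distortion))

        row = {
            "participant": participant, "session": session,
            "condition": condition, "order": order, "trial": trial,
            "phase": phase, "intended_object": intended,
            "intended_clock": intended_clock,
            "aim_offset": state.aim_offset, "latency_ms": latency,
            "endpoint_x": ex, "endpoint_y": ey, "amplitude": amplitude,
            "duration_ms": duration, "angle_to_intended": angle_int,
            "angle_to_optimal": angle_opt,
            "truth_onset_t": onset_t, "truth_offset_t": offset_t,
            "distorted_x": np.nan, "distorted_y": np.nan,
            "decoded_object": np.nan, "too_far": False,
            "decoding_error": np.nan, "outcome": np.nan,
            "feedback_kind": "", "feedback_x": np.nan, "feedback_y": np.nan,
            "colored_object": np.nan,
        }

        if is_feedback:
            dx_, dy_ = apply_distortion((ex, ey), scene)
            decoded = decode_object((dx_, dy_), scene)
            outcome = evaluate_trial(decoded, intended,
                                     distorted_endpoint=(dx_, dy_),
                                     scene=scene)
            fb = render_feedback(outcome, condition, scene)
            success = (decoded is not None) and not outcome.decoding_error
            fb_angle = (signed_angle((dx_, dy_), intended_clock)
                        if (dx_, dy_) != (0.0, 0.0) else 0.0)
            state = learner_update(state, fb_angle, success, rng)
            row.update({
                "distorted_x": float(dx_), "distorted_y": float(dy_),
                "decoded_object": -1.0 if decoded is None else float(decoded),
                "too_far": outcome.too_far,
                "decoding_error": (np.nan if outcome.decoding_error is None
                                   else float(outcome.decoding_error)),
                "outcome": float(success),
                "feedback_kind": fb.kind,
                "feedback_x": np.nan if fb.x is None else fb.x,
                "feedback_y": np.nan if fb.y is None else fb.y,
                "colored_object": (np.nan if fb.colored_object is None
                                   else float(fb.colored_object)),
            })

        # secondary corrective saccade toward the learner's current goal
        sec = None
        if sec_flags[i]:
            goal_clock = intended_clock + state.aim_offset
            gx, gy = from_clock(goal_clock, scene.object_radius)
            if fast:
                sx2 = float(gx + sec_noise[i, 0])
                sy2 = float(gy + sec_noise[i, 1])
                sec_amp = math.hypot(sx2 - ex, sy2 - ey)
                row.update({"sec_present": True,
                            "sec_latency_ms": float(sec_lats[i]),
                            "sec_endpoint_x": sx2, "sec_endpoint_y": sy2,
                            "sec_amplitude": sec_amp})
            else:
                sec_params = replace(kinematics,
                                     endpoint_noise_sd=kinematics.secondary_noise_sd,
                                     bow_coefficient=0.0)
                sec_lat = float(round(sec_lats[i]))
                if math.hypot(gx - ex, gy - ey) > 1e-6:
                    t2, x2, y2, truth2 = generate_saccade(
                        (ex, ey), (gx, gy), sec_params, rng,
                        t0=offset_t + sec_lat)
                    sec = (t2, x2, y2, truth2, sec_lat)
                    s2 = truth2["landing"]
                    row.update({"sec_present": True,
                                "sec_latency_ms": sec_lat,
                                "sec_endpoint_x": s2.x, "sec_endpoint_y": s2.y,
                                "sec_amplitude": truth2["amplitude"]})
        if "sec_present" not in row or not row.get("sec_present"):
            row.update({"sec_present": False, "sec_latency_ms": np.nan,
                        "sec_endpoint_x": np.nan, "sec_endpoint_y": np.nan,
                        "sec_amplitude": np.nan})
        rows.append(row)

        if not fast:
            primary = (tpr, xpr, ypr, truth)
            stream = _assemble_stream(fix_i + lat_i, float(fix_i),
                                      primary, sec, trial)
            if is_feedback:
                try:
                    off_t, _ = detect_offset_online(
                        stream,
                        after=detect_onset_online(stream, settings=detection)
                        or stream.fixation_off_t,
                        settings=detection)
                    stream.feedback_onset_t = off_t + detection.feedback_delay
                except Exception:
                    stream.feedback_onset_t = None
            streams.append(stream)

    trials = pd.DataFrame(rows, columns=_TRIAL_COLUMNS)
    return trials, streams, state


def simulate_experiment(n_participants: int = 22, savings: float = 0.9,
                        layout: SessionLayout = SessionLayout(),
                        kinematics: KinematicParams = KinematicParams(),
                        scene: SceneGeometry = SceneGeometry(),
                        learner: LearnerState = LearnerState(),
                        onset_delay_range: Tuple[int, int] = (20, 120),
                        seed=None, stream_mode: str = "none",
                        auto_mode: bool = True,
                        order_policy: str = "counterbalanced",
                        single_condition: Optional[str] = None):
    """Simulate a two-session cohort with counterbalanced feedback order.

    Half the participants receive motor feedback in session 1 and action
    feedback in session 2, the other half the reverse.  Learner mode follows
    the feedback type by default (motor -> error-based, action ->
    reward-based).  Per-participant learning-onset delays are drawn
    uniformly from ``onset_delay_range`` for session 1; in session 2 the
    learner starts at baseline aim but, once feedback resumes, retrieves
    ``savings`` times the previously learned offset with a proportionally
    raised learning rate and no onset delay (rapid reapplication).

    Returns ``(trials, streams)``: the cohort trial table and, when
    ``stream_mode='full'``, a dict ``(participant, session) -> list of
    GazeStream``.
    """
    if not 0.0 <= savings <= 1.0:
        raise ConfigurationError("savings must lie in [0, 1]")
    if order_policy not in ("counterbalanced", "motor_first", "action_first"):
        raise ConfigurationError(f"unknown order policy {order_policy!r}")
    if single_condition not in (None, "motor", "action"):
        raise ConfigurationError("single_condition must be motor or action")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_participants)
    frames = []
    streams: Dict[Tuple[int, int], list] = {}
    for pid in range(n_participants):
        rng = np.random.default_rng(children[pid])
        if single_condition is not None:
            order = f"{single_condition}_first"
            conds = (single_condition,)
        else:
            if order_policy == "counterbalanced":
                order = "motor_first" if pid % 2 == 0 else "action_first"
            else:
                order = order_policy
            conds = (("motor", "action") if order == "motor_first"
                     else ("action", "motor"))
        delay = int(rng.integers(onset_delay_range[0],
                                 onset_delay_range[1] + 1))
        learned = 0.0
        for sess, cond in enumerate(conds, start=1):
            mode = learner.mode
            if auto_mode:
                mode = "error_based" if cond == "motor" else "reward_based"
            if sess == 1:
                st = replace(learner, mode=mode, aim_offset=0.0,
                             onset_delay=delay, feedback_trials_seen=0,
                             memory=0.0, retrieval_offset=None)
            else:
                # retrieval scales with the savings coefficient: a fraction
                # of the learned offset is reinstated at the first feedback
                # trial, the learning rate is raised proportionally, and the
                # discovery delay shrinks toward zero (savings=0 reproduces
                # first-session learning conditions exactly)
                eta2 = min(1.0, learner.learning_rate * (1.0 + savings))
                delay2 = int(round((1.0 - savings) * int(
                    rng.integers(onset_delay_range[0],
                                 onset_delay_range[1] + 1))))
                st = replace(learner, mode=mode, aim_offset=0.0,
                             learning_rate=eta2, onset_delay=delay2,
                             feedback_trials_seen=0, memory=learned,
                             retrieval_offset=savings * learned)
            trials, strm, final = simulate_session(
                layout, st, kinematics, scene, rng, condition=cond,
                participant=pid, session=sess, order=order,
                stream_mode=stream_mode)
            if sess == 1:
                learned = final.aim_offset
            frames.append(trials)
            if strm is not None:
                streams[(pid, sess)] = strm
    cohort = pd.concat(frames, ignore_index=True)
    return cohort, (streams if stream_mode == "full" else None)
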