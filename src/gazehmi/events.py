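"""Saccade detection in gaze-sample streams and the trial validity filters.

Two detection roles share one set of criteria:

* the *online* role emulates the simulated interface: onset when eye speed
  exceeds 100 deg/s after travelling at least 3 deg from the fixation cross;
  offset when the mean speed over the last three samples drops below
  30 deg/s, the end point being the last of those three samples;
* the *offline* role parses a whole trial into primary and secondary
  saccades for analysis.  It uses the same 100 deg/s trigger but walks the
  onset back to the start of the motion (first sample of the surrounding run
  above a low threshold), which recovers the kinematic onset to within a few
  milliseconds at 1000 Hz.

Validity filters: primary saccades need an amplitude in [3.5, 10.5] deg, a
duration below 100 ms and a latency above 100 ms; secondary saccades need an
amplitude below 5 deg, a duration below 100 ms and a latency (relative to the
primary offset) between 100 and 500 ms inclusive.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .exceptions import StreamTooShortError, UnterminatedSaccadeError
from .geometry import ScreenPoint

__all__ = [
    "GazeStream",
    "SaccadeEvent",
    "DetectionSettings",
    "estimate_velocity",
    "detect_onset_online",
    "detect_offset_online",
    "parse_trial",
    "filter_primary",
    "filter_secondary",
]


@dataclass
class GazeStream:
    """One trial's uniformly sampled gaze positions (1 ms default spacing).

    ``t`` is in milliseconds and must be strictly increasing with a constant
    sampling interval; ``x``/``y`` are degrees of visual angle.
    ``fixation_off_t`` marks the go signal (fixation-cross offset) and is the
    latency reference for the primary saccade.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    fixation_off_t: float = 0.0
    feedback_onset_t: Optional[float] = None
    trial_id: Optional[int] = None

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.t.size == self.x.size == self.y.size):
            raise ValueError("t, x, y must have equal length")
        if self.t.size >= 2:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise ValueError("timestamps must be strictly increasing")
            if not np.allclose(dt, dt[0], rtol=0, atol=1e-9):
                raise ValueError("sampling interval must be constant "
                                 "(gaps indicate a read error)")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    def point(self, k: int) -> ScreenPoint:
        return ScreenPoint(float(self.x[k]), float(self.y[k]))


@dataclass
class SaccadeEvent:
    """One detected saccade with its derived metrics.

    Latency is referenced to the fixation-cross offset for primary saccades
    and to the primary saccade's offset for secondary saccades.
    """

    onset_t: float
    offset_t: float
    trajectory: np.ndarray            # (n, 2) ordered screen points
    endpoint: ScreenPoint
    amplitude: float                  # deg, Euclidean start -> end
    duration: float                   # ms
    latency: float                    # ms, see class docstring
    order: str                        # "primary" | "secondary" | "other"
    valid: bool = False

    def __post_init__(self):
        if self.offset_t <= self.onset_t:
            raise ValueError("offset must follow onset")


@dataclass(frozen=True)
class DetectionSettings:
    """Thresholds of the two-stage velocity detector."""

    onset_velocity: float = 100.0     # deg/s, trigger threshold
    min_travel: float = 3.0           # deg from fixation (online criterion)
    offset_velocity: float = 30.0     # deg/s, mean over last 3 samples
    offset_window: int = 3            # samples
    backtrack_velocity: float = 20.0  # deg/s, offline onset refinement
    secondary_window: float = 500.0   # ms after primary offset
    feedback_delay: float = 19.0      # ms detection-to-display (simulator)
    smooth: bool = False              # 5-sample moving average on speed


def estimate_velocity(stream: GazeStream, smooth: bool = False) -> np.ndarray:
    """Per-sample speed (deg/s) by two-point backward difference.

    ``speed[0]`` is set to 0.  The backward difference matches the causal
    online setting; an optional 5-sample moving average is available for
    noisy streams (off by default).
    """
    if stream.t.size < 3:
        raise StreamTooShortError("need at least 3 samples")
    dt_s = stream.dt / 1000.0
    step = np.hypot(np.diff(stream.x), np.diff(stream.y)) / dt_s
    speed = np.concatenate([[0.0], step])
    if smooth:
        kernel = np.ones(5) / 5.0
        speed = np.convolve(speed, kernel, mode="same")
    return speed


def detect_onset_online(stream: GazeStream,
                        fixation: ScreenPoint = ScreenPoint(0.0, 0.0),
                        settings: DetectionSettings = DetectionSettings(),
                        ) -> Optional[float]:
    """Online onset: first sample whose speed exceeds the velocity threshold
    with the eye at least ``min_travel`` deg away from the fixation cross.

    Returns the onset time in ms, or ``None`` if the criterion is never met.
    """
    speed = estimate_velocity(stream, smooth=settings.smooth)
    travel = np.hypot(stream.x - fixation.x, stream.y - fixation.y)
    hits = np.flatnonzero((speed > settings.onset_velocity)
                          & (travel >= settings.min_travel))
    if hits.size == 0:
        return None
    return float(stream.t[hits[0]])


def detect_offset_online(stream: GazeStream, after: float,
                         settings: DetectionSettings = DetectionSettings(),
                         ) -> Tuple[float, ScreenPoint]:
    """Online offset: earliest sample after ``after`` (ms) at which the mean
    speed over the trailing ``offset_window`` samples falls below the offset
    threshold.  The end point is that last sample itself.
    """
    speed = estimate_velocity(stream, smooth=settings.smooth)
    w = settings.offset_window
    start = int(np.searchsorted(stream.t, after, side="right"))
    if stream.t.size - start < w:
        raise UnterminatedSaccadeError("not enough samples after onset")
    mean3 = _trailing_mean(speed, w)
    candidates = np.flatnonzero(mean3[start:] < settings.offset_velocity)
    if candidates.size == 0:
        raise UnterminatedSaccadeError(
            "offset criterion never met before stream end")
    k = start + int(candidates[0])
    return float(stream.t[k]), stream.point(k)


def _trailing_mean(speed: np.ndarray, w: int) -> np.ndarray:
    """``out[k]`` = mean of ``speed[k-w+1..k]``; the first ``w-1`` entries,
    where no full window exists, are set to +inf so they never trigger."""
    kernel = np.ones(w) / w
    full = np.convolve(speed, kernel, mode="full")
    out = np.full(speed.size, np.inf)
    out[w - 1:] = full[w - 1:speed.size]
    return out


def _refine_onset(speed: np.ndarray, trigger_idx: int, floor_idx: int,
                  threshold: float) -> int:
    """Walk back from the trigger sample to the start of the motion run."""
    j = trigger_idx
    while j - 1 > floor_idx and speed[j - 1] > threshold:
        j -= 1
    return j


def parse_trial(stream: GazeStream,
                settings: DetectionSettings = DetectionSettings(),
                ) -> List[SaccadeEvent]:
    """Parse a trial stream into primary and secondary saccade events.

    The primary saccade is the first saccade after the fixation-cross offset;
    saccades whose onset falls within ``secondary_window`` ms of the primary
    offset are labelled secondary, later ones "other".  Latencies follow the
    :class:`SaccadeEvent` conventions.  Returns an empty list when no primary
    saccade is detected (the trial is then flagged and excluded downstream).
    """
    speed = estimate_velocity(stream, smooth=settings.smooth)
    n = speed.size
    events: List[SaccadeEvent] = []
    floor = int(np.searchsorted(stream.t, stream.fixation_off_t, side="left"))
    k = floor
    prev_offset_idx = floor - 1
    w = settings.offset_window
    mean_w = _trailing_mean(speed, w)
    while True:
        trig = np.flatnonzero(speed[k:] > settings.onset_velocity)
        if trig.size == 0:
            break
        trig_idx = k + int(trig[0])
        onset_idx = _refine_onset(speed, trig_idx, prev_offset_idx,
                                  settings.backtrack_velocity)
        below = np.flatnonzero(mean_w[trig_idx:] < settings.offset_velocity)
        if below.size == 0:
            break  # unterminated tail movement: ignore
        offset_idx = trig_idx + int(below[0])
        traj = np.column_stack([stream.x[onset_idx:offset_idx + 1],
                                stream.y[onset_idx:offset_idx + 1]])
        start = stream.point(onset_idx)
        end = stream.point(offset_idx)
        order = "primary" if not events else "secondary"
        if not events:
            latency = stream.t[onset_idx] - stream.fixation_off_t
        else:
            latency = stream.t[onset_idx] - events[0].offset_t
            if latency > settings.secondary_window:
                order = "other"
        ev = SaccadeEvent(
            onset_t=float(stream.t[onset_idx]),
            offset_t=float(stream.t[offset_idx]),
            trajectory=traj,
            endpoint=end,
            amplitude=float(np.hypot(end.x - start.x, end.y - start.y)),
            duration=float(stream.t[offset_idx] - stream.t[onset_idx]),
            latency=float(latency),
            order=order,
        )
        ev.valid = (filter_primary(ev) if order == "primary"
                    else filter_secondary(ev) if order == "secondary"
                    else False)
        events.append(ev)
        prev_offset_idx = offset_idx
        k = offset_idx + 1
        if k >= n:
            break
    return events


def filter_primary(e: SaccadeEvent,
                   amplitude_range: Tuple[float, float] = (3.5, 10.5),
                   max_duration: float = 100.0,
                   min_latency: float = 100.0) -> bool:
    """Primary-saccade validity: amplitude within [3.5, 10.5] deg, duration
    strictly below 100 ms, latency strictly above 100 ms."""
    lo, hi = amplitude_range
    return bool(lo <= e.amplitude <= hi
                and e.duration < max_duration
                and e.latency > min_latency)


def filter_secondary(e: SaccadeEvent,
                     max_amplitude: float = 5.0,
                     max_duration: float = 100.0,
                     latency_range: Tuple[float, float] = (100.0, 500.0),
                     ) -> bool:
    """Secondary-saccade validity: amplitude strictly below 5 deg, duration
    strictly below 100 ms, latency within [100, 500] ms inclusive."""
    lo, hi = latency_range
    return bool(e.amplitude < max_amplitude
                and e.duration < max_duration
                and lo <= e.latency <= hi)
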