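"""Task geometry of the simulated gaze-controlled object-selection interface.

The scene consists of ``n_objects`` small geometric objects whose centres of
gravity lie on an invisible circle around a central fixation cross.  Each
object owns a wedge-shaped *target area*: a circle segment around the object's
angular position extending from the fixation cross out to an invisible outer
circle.  The simulated interface decodes the intended object from the primary
saccade end point after adding a fixed clockwise rotation (the *distortion*)
that emulates a systematic error inherent to the system.

Coordinate convention
---------------------
Screen positions are Cartesian degrees of visual angle with the origin at the
fixation cross and y increasing upward.  Angular positions along the object
circle are *clock angles*: arc degrees measured clockwise from 12 o'clock
(+y axis), so ``theta(x, y) = atan2(x, y)`` mapped into ``[0, 360)``.  Signed
angular offsets are clockwise-positive and wrapped into ``(-180, 180]``.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np

from .exceptions import ConfigurationError

__all__ = [
    "OBJECT_NAMES",
    "ScreenPoint",
    "SceneGeometry",
    "DecodingOutcome",
    "FeedbackSpec",
    "build_scene",
    "clock_angle",
    "from_clock",
    "wrap_angle",
    "apply_distortion",
    "decode_object",
    "decode_objects",
    "evaluate_trial",
    "render_feedback",
]

#: Canonical object order, clockwise starting at 12 o'clock.
OBJECT_NAMES = (
    "star", "octagon", "triangle", "rhombus",
    "square", "hexagon", "circle", "parallelogram",
)


class ScreenPoint(NamedTuple):
    """A screen position in degrees of visual angle (origin = fixation cross)."""

    x: float
    y: float


def wrap_angle(angle):
    """Wrap angles (arc deg) into the half-open interval ``(-180, 180]``."""
    return 180.0 - (180.0 - np.asarray(angle, dtype=float)) % 360.0


def clock_angle(x, y):
    """Clock angle in ``[0, 360)``: arc deg clockwise from 12 o'clock (+y)."""
    return np.degrees(np.arctan2(x, y)) % 360.0


def from_clock(theta, radius):
    """Cartesian position of a clock angle ``theta`` at a given radius."""
    t = np.radians(np.asarray(theta, dtype=float))
    return radius * np.sin(t), radius * np.cos(t)


@dataclass(frozen=True)
class SceneGeometry:
    """The object array, target-area partition, and decoder distortion.

    Defaults follow the simulated interface's published configuration: eight
    objects on a 7-deg circle, target areas out to 9 deg spanning +-22.5 arc
    deg per object, and a constant clockwise 45 arc deg distortion.
    """

    n_objects: int = 8
    object_radius: float = 7.0        # deg visual angle
    area_outer_radius: float = 9.0    # deg visual angle
    distortion: float = 45.0          # arc deg, clockwise positive
    feedback_dot_diameter: float = 1.0  # deg visual angle
    object_names: Sequence[str] = field(default=OBJECT_NAMES)

    def __post_init__(self):
        if self.n_objects < 2:
            raise ConfigurationError("n_objects must be at least 2")
        if self.object_radius <= 0 or self.area_outer_radius <= 0:
            raise ConfigurationError("radii must be positive")
        if self.object_radius >= self.area_outer_radius:
            raise ConfigurationError(
                "object_radius must be smaller than area_outer_radius")
        if len(self.object_names) != self.n_objects:
            object.__setattr__(
                self, "object_names",
                tuple(f"object_{i}" for i in range(self.n_objects)))

    @property
    def area_half_width(self) -> float:
        """Angular half-width of each target area (arc deg): 180/n_objects."""
        return 180.0 / self.n_objects

    @property
    def object_clock_angles(self) -> np.ndarray:
        """Clock angles of the object centres, clockwise from 12 o'clock."""
        return np.arange(self.n_objects) * (360.0 / self.n_objects)

    def object_position(self, index: int) -> ScreenPoint:
        x, y = from_clock(self.object_clock_angles[index], self.object_radius)
        return ScreenPoint(float(x), float(y))

    def optimal_clock_angle(self, intended: int) -> float:
        """Clock angle of the aim point that cancels the distortion.

        Aiming ``distortion`` arc deg counterclockwise of the intended object
        places the distorted end point on the object itself.
        """
        return (self.object_clock_angles[intended] - self.distortion) % 360.0


@dataclass(frozen=True)
class DecodingOutcome:
    """Result of decoding one distorted saccade end point."""

    distorted_endpoint: ScreenPoint
    decoded_object: Optional[int]
    too_far: bool
    decoding_error: Optional[bool]  # None when nothing was decoded


@dataclass(frozen=True)
class FeedbackSpec:
    """The single post-saccadic feedback element shown on a feedback trial."""

    kind: str                       # "dot" | "color" | "message"
    x: Optional[float] = None       # dot centre (motor feedback)
    y: Optional[float] = None
    diameter: Optional[float] = None
    colored_object: Optional[int] = None  # action feedback
    message: Optional[str] = None


def build_scene(**config) -> SceneGeometry:
    """Construct a :class:`SceneGeometry`, validating all invariants.

    Parameters mirror the dataclass fields; omitted ones take the default
    (published) values.
    """
    return SceneGeometry(**config)


def apply_distortion(endpoint, scene: SceneGeometry):
    """Rotate an end point clockwise about the fixation cross by the scene
    distortion.  Radius is preserved exactly.

    Accepts a :class:`ScreenPoint` (returned as one) or x/y arrays.
    """
    d = np.radians(scene.distortion)
    cos_d, sin_d = np.cos(d), np.sin(d)
    if isinstance(endpoint, ScreenPoint) or (
            np.isscalar(endpoint[0]) and np.isscalar(endpoint[1])):
        x, y = float(endpoint[0]), float(endpoint[1])
        if not (np.isfinite(x) and np.isfinite(y)):
            raise ValueError("endpoint must be finite")
        return ScreenPoint(x * cos_d + y * sin_d, y * cos_d - x * sin_d)
    x = np.asarray(endpoint[0], dtype=float)
    y = np.asarray(endpoint[1], dtype=float)
    return x * cos_d + y * sin_d, y * cos_d - x * sin_d


def decode_objects(x, y, scene: SceneGeometry) -> np.ndarray:
    """Vectorised decoder: object index per point, ``-1`` for none (too far).

    A point is decoded to object ``i`` iff its radius does not exceed the
    outer target-area radius and the clockwise angular distance from the
    object's clock angle lies in ``[-half_width, +half_width)`` (half-open so
    the target areas tile the disk without overlap).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    r = np.hypot(x, y)
    theta = clock_angle(x, y)
    width = 360.0 / scene.n_objects
    idx = np.floor((theta + width / 2.0) / width).astype(int) % scene.n_objects
    return np.where(r <= scene.area_outer_radius, idx, -1)


def decode_object(distorted, scene: SceneGeometry) -> Optional[int]:
    """Decode a single distorted end point; ``None`` when too far."""
    x, y = float(distorted[0]), float(distorted[1])
    if not (np.isfinite(x) and np.isfinite(y)):
        raise ValueError("distorted endpoint must be finite")
    out = int(decode_objects(x, y, scene))
    return None if out < 0 else out


def evaluate_trial(decoded: Optional[int], intended: int,
                   distorted_endpoint=ScreenPoint(np.nan, np.nan),
                   scene: Optional[SceneGeometry] = None) -> DecodingOutcome:
    """Compare decoded and intended object for one trial.

    ``decoding_error`` is defined only when an object was decoded; a point
    outside every target area sets ``too_far`` (the interface then shows the
    "eye too far from any possible target" message instead of feedback).
    """
    n = scene.n_objects if scene is not None else 8
    if not (0 <= int(intended) < n):
        raise ConfigurationError(f"intended object index {intended} invalid")
    if decoded is None:
        return DecodingOutcome(ScreenPoint(*distorted_endpoint), None, True, None)
    return DecodingOutcome(ScreenPoint(*distorted_endpoint), int(decoded),
                           False, int(decoded) != int(intended))


TOO_FAR_MESSAGE = "eye too far from any possible target"


def render_feedback(outcome: DecodingOutcome, condition: str,
                    scene: SceneGeometry) -> FeedbackSpec:
    """Produce the single feedback element for a feedback trial.

    motor  -> red dot at the distorted end point;
    action -> the decoded object is coloured;
    nothing decoded -> the too-far message (in either condition).
    """
    if condition not in ("motor", "action"):
        raise ConfigurationError(f"unknown feedback condition {condition!r}")
    if outcome.too_far:
        return FeedbackSpec(kind="message", message=TOO_FAR_MESSAGE)
    if condition == "motor":
        return FeedbackSpec(kind="dot",
                            x=outcome.distorted_endpoint.x,
                            y=outcome.distorted_endpoint.y,
                            diameter=scene.feedback_dot_diameter)
    return FeedbackSpec(kind="color", colored_object=outcome.decoded_object)
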