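"""Per-attempt performance metrics.

Three indexes summarise one insertion attempt:

* **insertion error** — the angle between the needle axis and the skin
  tangent plane, evaluated at the freeze event, reported both as the raw
  insertion angle and as the absolute deviation from the 45-degree
  reference (a +/-5 degree tolerance band separates correct from wrong
  orientation);
* **duration** — seconds between the timer_start and timer_stop events;
* **number of mistakes** — debounced contacts with forbidden organs
  (vessels, colon/bowel, pancreas, lateral peritoneum) plus one if the
  orientation was wrong.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .anatomy import SkinFrame
from .haptics import SimResult, needle_axis
from .trajectory import Trajectory

__all__ = [
    "InsertionMetrics",
    "ScoringConfig",
    "ScoringError",
    "insertion_angle",
    "relative_error",
    "classify_orientation",
    "score_attempt",
]

DEFAULT_FORBIDDEN = frozenset(
    {"vasculature", "arteries_veins", "colon", "bowel", "pancreas", "lateral_peritoneum"}
)


class ScoringError(ValueError):
    """Raised when an attempt cannot be scored (e.g. missing timer events)."""


@dataclass(frozen=True)
class ScoringConfig:
    """Reference angle (degrees), tolerance band and the forbidden-organ set."""

    reference_angle: float = 45.0
    tolerance: float = 5.0
    forbidden_organs: frozenset[str] = DEFAULT_FORBIDDEN

    def __post_init__(self) -> None:
        if not 0.0 < self.reference_angle < 90.0:
            raise ValueError("reference_angle must be in (0, 90)")
        if self.tolerance < 0:
            raise ValueError("tolerance must be >= 0")


@dataclass
class InsertionMetrics:
    """The three performance indexes for one attempt."""

    insertion_angle: float  # degrees
    relative_error: float  # degrees
    duration: float  # s
    n_forbidden_contacts: int
    n_wrong_orientation: int
    preliminary_steps_done: bool = True
    subject: str | None = None
    group: str | None = None
    platform: str | None = None
    attempt: str | None = None

    @property
    def n_total_errors(self) -> int:
        return self.n_forbidden_contacts + self.n_wrong_orientation

    def as_dict(self) -> dict:
        return {
            "subject": self.subject,
            "group": self.group,
            "platform": self.platform,
            "attempt": self.attempt,
            "insertion_angle": self.insertion_angle,
            "relative_error": self.relative_error,
            "duration": self.duration,
            "n_forbidden_contacts": self.n_forbidden_contacts,
            "n_wrong_orientation": self.n_wrong_orientation,
            "n_total_errors": self.n_total_errors,
            "preliminary_steps_done": self.preliminary_steps_done,
        }


def insertion_angle(axis, skin_frame: SkinFrame) -> float:
    """Angle (degrees, in [0, 90]) between the needle axis and the skin plane.

    90 degrees is a perpendicular insertion, 0 an axis lying in the
    tangent plane; equivalently 90 minus the angle to the outward normal.
    """
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n < 1e-12:
        raise ValueError("zero needle axis")
    c = abs(float(np.dot(axis / n, skin_frame.normal)))
    return math.degrees(math.asin(min(c, 1.0)))


def relative_error(angle: float, config: ScoringConfig | None = None) -> float:
    """Absolute deviation (degrees) of the insertion angle from the reference."""
    config = config or ScoringConfig()
    return abs(angle - config.reference_angle)


def classify_orientation(angle: float, config: ScoringConfig | None = None) -> str:
    """"correct" iff the deviation is within the tolerance band (inclusive)."""
    config = config or ScoringConfig()
    return "correct" if relative_error(angle, config) <= config.tolerance else "wrong"


def score_attempt(
    trajectory: Trajectory,
    sim: SimResult,
    config: ScoringConfig | None = None,
    skin_frame: SkinFrame | None = None,
    preliminary_steps_done: bool | None = None,
) -> InsertionMetrics:
    """Score one attempt from its trajectory and simulation outputs.

    Duration is timer_stop minus timer_start (both required).  The
    insertion angle is evaluated from the pose at the freeze event
    (falling back to the final sample with a warning).  Forbidden
    contacts come debounced from the simulation's contact log; wrong
    orientation contributes at most one mistake per attempt.
    """
    config = config or ScoringConfig()
    skin_frame = skin_frame or SkinFrame()

    t0 = trajectory.event_time("timer_start")
    t1 = trajectory.event_time("timer_stop")
    if t0 is None or t1 is None:
        raise ScoringError("attempt is missing timer_start/timer_stop events")

    pose = trajectory.sample_at_event("freeze")
    if pose is None:
        warnings.warn("no freeze event; evaluating angle at the final sample", stacklevel=2)
        pose = trajectory.samples[-1]
    angle = insertion_angle(needle_axis(pose.quaternion), skin_frame)
    err = relative_error(angle, config)
    wrong = int(classify_orientation(angle, config) == "wrong")

    n_contacts = sum(
        1 for c in sim.contacts if c.forbidden and c.organ in config.forbidden_organs
    )

    if preliminary_steps_done is None:
        steps = {s.event for s in trajectory.samples}
        preliminary_steps_done = {"step1", "step2", "step3"} <= steps

    md = trajectory.metadata
    return InsertionMetrics(
        insertion_angle=angle,
        relative_error=err,
        duration=t1 - t0,
        n_forbidden_contacts=n_contacts,
        n_wrong_orientation=wrong,
        preliminary_steps_done=preliminary_steps_done,
        subject=md.get("subject"),
        group=md.get("group"),
        platform=md.get("platform"),
        attempt=md.get("attempt"),
    )
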