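"""Needle-pose trajectory I/O and the synthetic-trainee generator.

A :class:`Trajectory` is an ordered stream of timestamped needle poses
(tip position in skin-frame mm, unit orientation quaternion) with optional
event markers following the two-attempt insertion protocol:

    step1 -> step2 -> step3 -> timer_start -> (insertion) -> freeze -> timer_stop

The generator stands in for human participants: a :class:`TraineeProfile`
gives each synthetic trainee an insertion-angle bias and variability, an
axial speed, lateral tremor and an overshoot probability; attempt B
applies a multiplicative ``learning_gain`` (< 1 improves) to the bias,
the variability and the task duration, emulating the within-session
learning effect the two-attempt design measures.  All randomness flows
through named streams derived from ``(seed, subject, attempt)``, so
cohorts are reproducible and extensible without reshuffling.
"""

from __future__ import annotations

import csv
import json
import math
import os
from dataclasses import dataclass, field, replace

import numpy as np

from .anatomy import Anatomy, generate_anatomy

__all__ = [
    "PoseSample",
    "Trajectory",
    "TraineeProfile",
    "ProfileDistribution",
    "TrajectoryValidationError",
    "read_trajectory",
    "write_trajectory",
    "generate_attempt",
    "generate_cohort",
    "EVENTS",
]

EVENTS = ("timer_start", "timer_stop", "freeze", "step1", "step2", "step3")

REFERENCE_ANGLE_DEG = 45.0


class TrajectoryValidationError(ValueError):
    """Raised for malformed trajectories; names the offending row."""


@dataclass
class PoseSample:
    t: float
    position: np.ndarray
    quaternion: np.ndarray  # (qw, qx, qy, qz), unit norm
    event: str | None = None

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.quaternion = np.asarray(self.quaternion, dtype=float)


@dataclass
class Trajectory:
    """Ordered pose stream plus study metadata (subject, group, platform, attempt)."""

    samples: list[PoseSample]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        prev_t = -math.inf
        n_start = n_stop = 0
        t_start = t_stop = None
        for i, s in enumerate(self.samples, start=1):
            if s.t <= prev_t:
                raise TrajectoryValidationError(
                    f"row {i}: timestamp {s.t} not strictly increasing"
                )
            prev_t = s.t
            qn = float(np.linalg.norm(s.quaternion))
            if abs(qn - 1.0) > 1e-3:
                raise TrajectoryValidationError(f"row {i}: quaternion norm {qn:.4g} != 1")
            if s.event == "timer_start":
                n_start += 1
                t_start = s.t
            elif s.event == "timer_stop":
                n_stop += 1
                t_stop = s.t
        if n_start > 1 or n_stop > 1:
            raise TrajectoryValidationError("more than one timer_start/timer_stop event")
        if t_start is not None and t_stop is not None and t_start >= t_stop:
            raise TrajectoryValidationError("timer_start must precede timer_stop")

    def event_time(self, event: str) -> float | None:
        for s in self.samples:
            if s.event == event:
                return s.t
        return None

    def sample_at_event(self, event: str) -> PoseSample | None:
        for s in self.samples:
            if s.event == event:
                return s
        return None

    @property
    def duration(self) -> float | None:
        t0, t1 = self.event_time("timer_start"), self.event_time("timer_stop")
        if t0 is None or t1 is None:
            return None
        return t1 - t0


@dataclass(frozen=True)
class TraineeProfile:
    """Motor behaviour of one synthetic trainee.

    ``angle_bias``/``angle_sd`` (degrees) shape the insertion angle drawn
    as Normal(45 + bias, sd); ``speed`` (mm/s) the axial advance rate;
    ``speed_jitter_sd`` a lognormal per-attempt speed wobble;
    ``overshoot_prob`` the chance of driving past the peritoneum into the
    bowel; ``lateral_tremor_sd`` (mm) hand tremor orthogonal to the axis;
    ``learning_gain`` in (0, 1] multiplies bias, sd and duration for
    attempt B (1 = no learning).
    """

    angle_bias: float = 0.0
    angle_sd: float = 3.0
    speed: float = 0.8
    speed_jitter_sd: float = 0.1
    overshoot_prob: float = 0.1
    lateral_tremor_sd: float = 0.3
    learning_gain: float = 0.8

    def __post_init__(self) -> None:
        if self.angle_sd < 0 or self.lateral_tremor_sd < 0 or self.speed_jitter_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if not 0.0 <= self.overshoot_prob <= 1.0:
            raise ValueError("overshoot_prob must be in [0, 1]")
        if not 0.0 < self.learning_gain <= 1.0:
            raise ValueError("learning_gain must be in (0, 1]")
        if self.speed <= 0:
            raise ValueError("speed must be > 0")


# ---------------------------------------------------------------------------
# CSV / JSON I/O

_CSV_HEADER = ["t", "px", "py", "pz", "qw", "qx", "qy", "qz", "event"]


def write_trajectory(trajectory: Trajectory, path: str | os.PathLike) -> None:
    """Write CSV (``.csv``) or JSON (anything else) per the declared schema."""
    path = os.fspath(path)
    if path.lower().endswith(".csv"):
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(_CSV_HEADER)
            for s in trajectory.samples:
                w.writerow(
                    [f"{s.t:.6f}", *(f"{x:.9g}" for x in s.position),
                     *(f"{x:.9g}" for x in s.quaternion), s.event or ""]
                )
    else:
        payload = {
            "metadata": trajectory.metadata,
            "samples": [
                {
                    "t": round(s.t, 6),
                    "position": [float(x) for x in s.position],
                    "quaternion": [float(x) for x in s.quaternion],
                    "event": s.event,
                }
                for s in trajectory.samples
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def read_trajectory(path: str | os.PathLike) -> Trajectory:
    """Read a trajectory from CSV or JSON; validates and names bad rows."""
    path = os.fspath(path)
    samples: list[PoseSample] = []
    metadata: dict = {}
    if path.lower().endswith(".csv"):
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            missing = set(_CSV_HEADER[:-1]) - set(reader.fieldnames or [])
            if missing:
                raise TrajectoryValidationError(f"missing CSV columns: {sorted(missing)}")
            for i, row in enumerate(reader, start=1):
                try:
                    samples.append(
                        PoseSample(
                            t=float(row["t"]),
                            position=[float(row["px"]), float(row["py"]), float(row["pz"])],
                            quaternion=[float(row["qw"]), float(row["qx"]),
                                        float(row["qy"]), float(row["qz"])],
                            event=row.get("event") or None,
                        )
                    )
                except (TypeError, ValueError) as exc:
                    raise TrajectoryValidationError(f"row {i}: {exc}") from exc
    else:
        with open(path) as fh:
            payload = json.load(fh)
        metadata = payload.get("metadata", {})
        for i, rec in enumerate(payload["samples"], start=1):
            try:
                samples.append(
                    PoseSample(t=float(rec["t"]), position=rec["position"],
                               quaternion=rec["quaternion"], event=rec.get("event"))
                )
            except (TypeError, ValueError, KeyError) as exc:
                raise TrajectoryValidationError(f"row {i}: {exc}") from exc
    return Trajectory(samples=samples, metadata=metadata)


# ---------------------------------------------------------------------------
# Synthetic attempt generation


def _attempt_rng(seed: int, subject: int, attempt: str, purpose: int = 0):
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) % (2**31), int(subject), 0 if attempt == "A" else 1,
                                purpose])
    )


def generate_attempt(
    profile: TraineeProfile,
    anatomy: Anatomy,
    attempt: str = "A",
    seed: int = 0,
    subject: int = 0,
    n_insertion_samples: int = 80,
    metadata: dict | None = None,
) -> Trajectory:
    """One synthetic insertion attempt as a straight-line trajectory.

    The insertion angle is drawn from Normal(45 + bias, sd) degrees (bias
    and sd scaled by ``learning_gain`` for attempt B); the needle advances
    at the profile speed (also learning-scaled for B) from a start pose
    above the skin to just past the peritoneum, with an overshoot branch
    driving into the bowel before retracting.  Protocol events are emitted
    in order; the orientation quaternion is constant (orient, then push).
    """
    if attempt not in ("A", "B"):
        raise ValueError("attempt must be 'A' or 'B'")
    g = profile.learning_gain if attempt == "B" else 1.0
    rng = _attempt_rng(seed, subject, attempt)

    bias = profile.angle_bias * g
    sd = profile.angle_sd * g
    angle = rng.normal(REFERENCE_ANGLE_DEG + bias, sd) if sd > 0 else REFERENCE_ANGLE_DEG + bias
    angle = float(np.clip(angle, 10.0, 89.0))

    theta = math.radians(angle)
    u = np.array([0.0, math.cos(theta), -math.sin(theta)])  # into the tissue
    quat = np.array([0.0, *u])
    quat = quat / np.linalg.norm(quat)

    wall = anatomy.total_thickness
    nominal_depth = wall + 3.0  # mm past the peritoneum, inside the cavity
    overshoot = bool(rng.random() < profile.overshoot_prob)
    target_depth = wall + 18.0 if overshoot else nominal_depth  # into the bowel loops

    sin_t = math.sin(theta)
    approach = 10.0  # mm of free travel above the skin along the axis
    path_len = approach + target_depth / sin_t
    speed = profile.speed / g
    if profile.speed_jitter_sd > 0:
        speed *= float(np.exp(rng.normal(0.0, profile.speed_jitter_sd)))
    t_insert = path_len / speed

    entry = np.zeros(3)
    start = entry - approach * u

    samples: list[PoseSample] = []
    t = 0.0
    for step in ("step1", "step2", "step3"):
        samples.append(PoseSample(t=t, position=start.copy(), quaternion=quat, event=step))
        t += 0.5
    samples.append(PoseSample(t=t, position=start.copy(), quaternion=quat, event="timer_start"))
    t_start = t

    n_ins = max(int(n_insertion_samples), 8)
    dt = t_insert / n_ins
    tremor = profile.lateral_tremor_sd
    e1 = np.array([1.0, 0.0, 0.0])  # orthogonal to u (u has no x component)
    e2 = np.cross(u, e1)
    for i in range(1, n_ins + 1):
        pos = start + u * (path_len * i / n_ins)
        if tremor > 0:
            pos = pos + rng.normal(0, tremor) * e1 + rng.normal(0, tremor) * e2
        t += dt
        samples.append(PoseSample(t=t, position=pos, quaternion=quat))

    if overshoot:  # pull back to the nominal depth before freezing
        back = (target_depth - nominal_depth) / sin_t
        tip = start + u * path_len
        for i in range(1, 9):
            t += 0.25
            samples.append(
                PoseSample(t=t, position=tip - back * (i / 8) * u, quaternion=quat)
            )

    final = start + u * (approach + nominal_depth / sin_t)
    t += 0.5
    samples.append(PoseSample(t=t, position=final.copy(), quaternion=quat, event="freeze"))
    t += 2.0  # self-assessment dwell
    samples.append(PoseSample(t=t, position=final.copy(), quaternion=quat, event="timer_stop"))

    meta = dict(metadata or {})
    meta.setdefault("subject", f"S{subject:02d}")
    meta["attempt"] = attempt
    meta["seed"] = int(seed)
    meta["angle_deg"] = angle
    meta["overshoot"] = overshoot
    meta["duration_s"] = t - t_start
    return Trajectory(samples=samples, metadata=meta)


@dataclass(frozen=True)
class ProfileDistribution:
    """Between-subject distribution a cohort's profiles are drawn from.

    ``bias_mu``/``bias_sd`` (degrees) spread the per-subject angle bias;
    the remaining fields centre the corresponding :class:`TraineeProfile`
    parameters, with mild lognormal variation for speed.  Defaults for the
    two groups reflect that experienced operators aim more accurately,
    move faster and overshoot less than students.
    """

    bias_mu: float = 0.0
    bias_sd: float = 5.0
    angle_sd: float = 3.0
    speed: float = 0.7
    speed_subject_sd: float = 0.15
    speed_jitter_sd: float = 0.1
    overshoot_prob: float = 0.2
    lateral_tremor_sd: float = 0.3
    learning_gain: float = 0.8

    def sample(self, rng: np.random.Generator) -> TraineeProfile:
        return TraineeProfile(
            angle_bias=float(rng.normal(self.bias_mu, self.bias_sd)),
            angle_sd=abs(float(rng.normal(self.angle_sd, 0.3 * self.angle_sd))),
            speed=float(self.speed * np.exp(rng.normal(0, self.speed_subject_sd))),
            speed_jitter_sd=self.speed_jitter_sd,
            overshoot_prob=self.overshoot_prob,
            lateral_tremor_sd=self.lateral_tremor_sd,
            learning_gain=self.learning_gain,
        )


GROUP_DEFAULTS: dict[str, ProfileDistribution] = {
    "experienced": ProfileDistribution(
        bias_sd=4.0, angle_sd=2.5, speed=0.85, overshoot_prob=0.1, learning_gain=0.85
    ),
    "student": ProfileDistribution(
        bias_sd=6.0, angle_sd=3.5, speed=0.6, overshoot_prob=0.25, learning_gain=0.75
    ),
}


def generate_cohort(
    n_subjects: int = 14,
    group_mix: float = 0.5,
    profile_distribution: dict[str, ProfileDistribution] | None = None,
    seed: int = 0,
    anatomy: Anatomy | None = None,
    n_insertion_samples: int = 80,
) -> list[tuple[Trajectory, Trajectory]]:
    """Paired attempt-A/attempt-B trajectories for a synthetic cohort.

    The first ``round(group_mix * n)`` subjects are "experienced", the
    rest "student"; within each group platforms alternate between the two
    simulator implementations.  Each subject's profile is drawn once
    (shared individual effect) and reused for both attempts, with the
    learning gain applied inside :func:`generate_attempt` for attempt B.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if anatomy is None:
        anatomy = generate_anatomy(seed=seed)
    dists = dict(GROUP_DEFAULTS)
    if profile_distribution:
        dists.update(profile_distribution)
    n_exp = int(round(group_mix * n_subjects))
    pairs: list[tuple[Trajectory, Trajectory]] = []
    for s in range(n_subjects):
        group = "experienced" if s < n_exp else "student"
        platform = "OH" if (s % 2 == 0) else "CHAI3D"
        prof_rng = _attempt_rng(seed, s, "A", purpose=99)
        profile = dists[group].sample(prof_rng)
        meta = {"subject": f"S{s:02d}", "group": group, "platform": platform}
        tA = generate_attempt(profile, anatomy, "A", seed=seed, subject=s,
                              n_insertion_samples=n_insertion_samples, metadata=dict(meta))
        tB = generate_attempt(profile, anatomy, "B", seed=seed, subject=s,
                              n_insertion_samples=n_insertion_samples, metadata=dict(meta))
        pairs.append((tA, tB))
    return pairs


def null_profile_distributions() -> dict[str, ProfileDistribution]:
    """Group distributions with the learning effect switched off.

    Attempt A and B then differ only by independent symmetric draws, so
    per-subject paired differences are centred at zero — the null
    condition for calibrating the paired test's type-I error.
    """
    return {name: replace(d, learning_gain=1.0) for name, d in GROUP_DEFAULTS.items()}
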