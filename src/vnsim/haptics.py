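"""Haptic force model for layered needle insertion.

The force a trainee feels is composed of:

* a **fulcrum constraint**: once the needle tip has pierced the skin at
  insertion point ``r``, lateral motion of the device is resisted by a
  spring ``F = k (p' - p)`` pulling the device position ``p`` back toward
  its orthogonal projection ``p'`` on the needle line (through ``r`` along
  the needle axis), so the tool can travel back and forth along the
  insertion direction but not sideways;
* an **axial layered response**: each wall layer contributes a membrane
  spring at its entry surface (force grows with penetration until the
  layer's pop-through threshold, then releases — the "pop"), plus bulk
  damping proportional to axial velocity and a constant friction opposing
  motion while the tip travels through the layer.

Layer parameters are dimensionless 0-1 values; :class:`HapticConfig` maps
them to physical units.  The two clinically salient pops — linea alba and
peritoneum — are flagged ``distinct``; skin puncture is logged but not
counted among them.

:func:`simulate_trajectory` replays a recorded pose stream through the
model and returns per-sample force decompositions, pop events and a
debounced forbidden-organ contact log.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .anatomy import Anatomy, ConfigurationError, TissueLayer
from .trajectory import Trajectory

__all__ = [
    "HapticConfig",
    "NeedleState",
    "ForceSample",
    "PopEvent",
    "ContactEvent",
    "SimResult",
    "InvalidPoseError",
    "needle_axis",
    "fulcrum_force",
    "pop_threshold",
    "axial_response",
    "simulate_trajectory",
]

#: below this axial speed (mm/s) friction is in the static regime
STATIC_VELOCITY_DEADBAND = 0.1


class InvalidPoseError(ValueError):
    """Raised for zero/degenerate quaternions or invalid needle states."""


@dataclass(frozen=True)
class HapticConfig:
    """Maps the 0-1 tissue parameters to physical units.

    f_max is the device force scale: a pop-through of 1.0 means the
    membrane yields at the device's nominal maximum continuous force
    (3.3 N for the 3-DoF stylus class this model targets).  The remaining
    scales are declared conventions, config-exposed because the tissue
    table itself is unitless.
    """

    k_fulcrum: float = 0.5  # N/mm lateral spring
    f_max: float = 3.3  # N
    stiffness_scale: float = 1.0  # N/mm per unit stiffness
    damping_scale: float = 0.01  # N*s/mm per unit damping
    friction_scale: float = 1.0  # N per unit friction
    literal_fulcrum_sign: bool = False  # render k(p - p') instead of k(p' - p)

    def __post_init__(self) -> None:
        for name in ("k_fulcrum", "f_max", "stiffness_scale", "damping_scale", "friction_scale"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"haptic scale {name} must be > 0")


@dataclass
class NeedleState:
    """Needle pose at one instant.

    ``r`` is the insertion point, fixed once the skin is pierced; ``p`` is
    the device/proxy probe position; ``Q = (qw, qx, qy, qz)`` the unit
    orientation quaternion; ``depth`` the penetration measured along the
    skin normal (mm, >= 0 after skin contact).
    """

    p: np.ndarray
    Q: np.ndarray
    r: np.ndarray | None = None
    depth: float = 0.0
    frozen: bool = False

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        self.Q = np.asarray(self.Q, dtype=float)
        n = np.linalg.norm(self.Q)
        if abs(n - 1.0) > 1e-6:
            raise InvalidPoseError(f"quaternion norm {n:.3g} != 1")
        if self.r is not None:
            self.r = np.asarray(self.r, dtype=float)


@dataclass
class PopEvent:
    """Rupture of one layer membrane.

    ``threshold_force`` is pop_through * f_max for that layer; ``distinct``
    marks the clinically counted pops (linea alba, peritoneum).
    """

    t: float
    layer: str
    threshold_force: float
    distinct: bool


@dataclass
class ContactEvent:
    """Debounced contact of the needle tip with an organ."""

    t: float
    organ: str
    position: np.ndarray
    forbidden: bool


@dataclass
class ForceSample:
    """Force decomposition at one timestep; f_total is the vector sum."""

    t: float
    f_total: np.ndarray
    f_fulcrum: np.ndarray
    f_axial_spring: np.ndarray
    f_damping: np.ndarray
    f_friction: np.ndarray
    layer: str
    events: list[str] = field(default_factory=list)


def needle_axis(Q) -> np.ndarray:
    """Needle direction from the orientation quaternion.

    The vector part (qx, qy, qz), normalised, is taken as the axis; when
    the vector part is numerically zero (pure-scalar quaternions such as
    the identity) the fallback is the device z-axis rotated by Q.
    """
    Q = np.asarray(Q, dtype=float)
    n = np.linalg.norm(Q)
    if n < 1e-12:
        raise InvalidPoseError("zero quaternion has no orientation")
    qw, qx, qy, qz = Q / n
    v = np.array([qx, qy, qz])
    nv = np.linalg.norm(v)
    if nv > 1e-6:
        return v / nv
    # rotate (0,0,1) by Q: standard quaternion sandwich, expanded
    return np.array(
        [2 * (qx * qz + qw * qy), 2 * (qy * qz - qw * qx), 1 - 2 * (qx * qx + qy * qy)]
    )


def fulcrum_force(r, p, Q, k_fulcrum: float, literal_sign: bool = False) -> np.ndarray:
    """Lateral restoring force of the fulcrum constraint.

    Projects ``p`` onto the line through ``r`` along ``needle_axis(Q)`` and
    returns ``k (p' - p)`` — the restoring pull toward the line, orthogonal
    to the axis, zero iff ``p`` lies on it.  With ``literal_sign`` the
    opposite (outward) sign is returned for fidelity comparisons.
    """
    r = np.asarray(r, dtype=float)
    p = np.asarray(p, dtype=float)
    axis = needle_axis(Q)
    proj = r + np.dot(p - r, axis) * axis
    f = k_fulcrum * (proj - p)
    return -f if literal_sign else f


def pop_threshold(pop_through: float, f_max: float) -> float:
    """Membrane rupture force: pop_through * f_max (0 disables the membrane)."""
    if not 0.0 <= pop_through <= 1.0:
        raise ConfigurationError(f"pop_through={pop_through} outside [0, 1]")
    if f_max <= 0:
        raise ConfigurationError("f_max must be > 0")
    return pop_through * f_max


# ---------------------------------------------------------------------------
# Axial layered response


class _StackInfo:
    """Pre-extracted per-layer floats so the per-sample loop stays cheap."""

    __slots__ = ("names", "starts", "ends", "stiff", "damp", "fric_s", "fric_d",
                 "thresholds", "distinct", "total")

    def __init__(self, layers: list[TissueLayer], config: HapticConfig):
        self.names = [l.name for l in layers]
        self.starts = [l.depth_start for l in layers]
        self.ends = [l.depth_end for l in layers]
        self.stiff = [config.stiffness_scale * l.stiffness for l in layers]
        self.damp = [config.damping_scale * l.damping for l in layers]
        self.fric_s = [config.friction_scale * l.static_friction for l in layers]
        self.fric_d = [config.friction_scale * l.dynamic_friction for l in layers]
        self.thresholds = [pop_threshold(l.pop_through, config.f_max) for l in layers]
        self.distinct = [l.distinct_pop for l in layers]
        self.total = layers[-1].depth_end

    def layer_index(self, depth: float) -> int:
        """Index of the layer containing depth, -1 outside, -2 in the cavity."""
        if depth < 0.0:
            return -1
        if depth >= self.total:
            return -2
        for i, e in enumerate(self.ends):
            if depth < e:
                return i
        return -2


def _axial_core(depth: float, velocity: float, info: _StackInfo, popped: set[str],
                t: float = 0.0):
    """Scalar membrane + bulk response at one (depth, velocity) sample.

    Returns (spring, damping, friction) as signed scalars along the
    insertion direction (negative = resisting insertion) and the list of
    PopEvents fired at this sample, plus the effective bulk-layer label.

    The tip is held by the shallowest un-popped membrane it presses on:
    its spring loads with membrane penetration and releases when it
    reaches the pop threshold (the membrane then stays popped for this
    traversal).  Bulk damping/friction come from the layer the tip
    effectively occupies (above the blocking membrane if one is loaded).
    """
    events: list[PopEvent] = []
    spring = 0.0
    effective_depth = depth
    # membranes in traversal order; a loaded membrane blocks deeper ones
    for i in range(len(info.names)):
        thr = info.thresholds[i]
        if thr <= 0.0 or info.names[i] in popped:
            continue
        start = info.starts[i]
        if depth <= start:
            break  # deeper membranes not reached yet
        pen = depth - start
        load = info.stiff[i] * pen
        if load >= thr:
            popped.add(info.names[i])
            events.append(PopEvent(t=t, layer=info.names[i], threshold_force=thr,
                                   distinct=info.distinct[i]))
            continue  # released; deeper membranes may now engage
        spring = -load  # resists insertion
        effective_depth = start  # tip held at the membrane
        break

    # bulk layer: just above a loaded membrane, else the layer containing depth
    if spring < 0.0:
        li = info.layer_index(effective_depth - 1e-9)
    else:
        li = info.layer_index(depth)

    damping = 0.0
    friction = 0.0
    if li >= 0:
        damping = -info.damp[li] * velocity
        if abs(velocity) > STATIC_VELOCITY_DEADBAND:
            friction = -info.fric_d[li] if velocity > 0 else info.fric_d[li]
        # static regime: the bound resists motion onset; no force at rest
    if li == -1:
        label = "outside"
    elif li == -2:
        label = "cavity"
    else:
        label = info.names[li]
    return spring, damping, friction, events, label


def axial_response(state: NeedleState, stack, axial_velocity: float,
                   config: HapticConfig, popped: set[str] | None = None):
    """Axial spring/damping/friction response at one needle state.

    ``stack`` is a list of :class:`TissueLayer` (contiguous, from depth 0)
    or an :class:`Anatomy`.  ``popped`` carries the membrane-rupture state
    between calls and is mutated in place when a pop fires.

    Returns ``(f_axial_spring, f_damping, f_friction, events)`` where the
    force terms are signed scalars along the insertion direction (negative
    values resist insertion) and ``events`` are the :class:`PopEvent`\\ s
    fired at this sample.
    """
    layers = stack.layers if isinstance(stack, Anatomy) else list(stack)
    info = _StackInfo(layers, config)
    if popped is None:
        popped = set()
    if state.depth < 0.0 and "peritoneum" in popped:
        raise InvalidPoseError("negative depth after cavity entry")
    spring, damping, friction, events, _ = _axial_core(
        state.depth, axial_velocity, info, popped
    )
    return spring, damping, friction, events


# ---------------------------------------------------------------------------
# Trajectory replay


@dataclass
class SimResult:
    """Array-backed output of :func:`simulate_trajectory`.

    Per-sample arrays (n rows, forces in N as 3-vectors in the skin frame)
    plus the pop-event and contact logs.  ``samples`` materialises the
    per-timestep :class:`ForceSample` view.
    """

    t: np.ndarray
    f_total: np.ndarray
    f_fulcrum: np.ndarray
    f_axial_spring: np.ndarray
    f_damping: np.ndarray
    f_friction: np.ndarray
    layer: list[str]
    sample_events: list[list[str]]
    pops: list[PopEvent]
    contacts: list[ContactEvent]
    depth: np.ndarray
    insertion_point: np.ndarray | None

    @property
    def samples(self) -> list[ForceSample]:
        return [
            ForceSample(
                t=float(self.t[i]),
                f_total=self.f_total[i],
                f_fulcrum=self.f_fulcrum[i],
                f_axial_spring=self.f_axial_spring[i],
                f_damping=self.f_damping[i],
                f_friction=self.f_friction[i],
                layer=self.layer[i],
                events=self.sample_events[i],
            )
            for i in range(len(self.t))
        ]

    @property
    def distinct_pops(self) -> list[PopEvent]:
        return [e for e in self.pops if e.distinct]

    @property
    def forbidden_contacts(self) -> list[ContactEvent]:
        return [c for c in self.contacts if c.forbidden]


def simulate_trajectory(anatomy: Anatomy, trajectory: Trajectory,
                        config: HapticConfig | None = None) -> SimResult:
    """Replay a pose stream through the layered force model.

    One force decomposition per input pose; the fulcrum force engages once
    the tip pierces the skin plane and acts about the (frozen) insertion
    point; axial terms are resolved along the needle axis oriented into
    the tissue.  Pop events and debounced forbidden-organ contacts are
    timestamped.  Deterministic: identical inputs give identical outputs.
    """
    if config is None:
        config = HapticConfig()
    tv = np.asarray([s.t for s in trajectory.samples], dtype=float)
    if len(tv) == 0:
        raise ValueError("empty trajectory")
    if np.any(np.diff(tv) <= 0):
        raise ValueError("trajectory timestamps must be strictly increasing")
    P = np.asarray([s.position for s in trajectory.samples], dtype=float)
    Qs = np.asarray([s.quaternion for s in trajectory.samples], dtype=float)
    n = len(tv)

    frame = anatomy.skin_frame
    origin = np.asarray(frame.origin, dtype=float)
    normal = np.asarray(frame.normal, dtype=float)
    depths = -((P - origin) @ normal)

    # needle axes (vectorised vector-part normalisation; fallback per-row)
    vparts = Qs[:, 1:]
    vnorm = np.linalg.norm(vparts, axis=1)
    axes = np.zeros((n, 3))
    ok = vnorm > 1e-6
    axes[ok] = vparts[ok] / vnorm[ok, None]
    for i in np.nonzero(~ok)[0]:
        axes[i] = needle_axis(Qs[i])
    # orient axes into the tissue (along -normal) for the axial decomposition
    flip = (axes @ normal) > 0
    u = np.where(flip[:, None], -axes, axes)

    # insertion point: first crossing of the skin plane, interpolated
    inserted = depths > 0
    r: np.ndarray | None = None
    if inserted.any():
        i1 = int(np.argmax(inserted))
        if i1 == 0:
            r = P[0] - depths[0] * (-normal)  # project back to the plane
        else:
            a, b = P[i1 - 1], P[i1]
            da, db = depths[i1 - 1], depths[i1]
            w = -da / (db - da)
            r = a + w * (b - a)

    # fulcrum force (vectorised): active while the tip is below the skin
    f_ful = np.zeros((n, 3))
    if r is not None:
        rel = P - r
        proj = r + (np.einsum("ij,ij->i", rel, axes))[:, None] * axes
        f = config.k_fulcrum * (proj - P)
        if config.literal_fulcrum_sign:
            f = -f
        f_ful[inserted] = f[inserted]

    # axial velocity from finite differences of depth
    vel = np.zeros(n)
    if n > 1:
        vel[1:] = np.diff(depths) / np.diff(tv)
        vel[0] = vel[1]

    info = _StackInfo(anatomy.layers, config)
    popped: set[str] = set()
    pops: list[PopEvent] = []
    f_spr = np.zeros((n, 3))
    f_dmp = np.zeros((n, 3))
    f_frc = np.zeros((n, 3))
    labels: list[str] = []
    sample_events: list[list[str]] = [[] for _ in range(n)]
    for i in range(n):
        s, dmp, frc, events, label = _axial_core(
            float(depths[i]), float(vel[i]), info, popped, t=float(tv[i])
        )
        if s:
            f_spr[i] = s * u[i]
        if dmp:
            f_dmp[i] = dmp * u[i]
        if frc:
            f_frc[i] = frc * u[i]
        labels.append(label)
        for e in events:
            pops.append(e)
            kind = "pop" if e.distinct else "puncture"
            sample_events[i].append(f"{kind}:{e.layer}")

    # forbidden-organ contacts (vectorised sphere tests, debounced per organ)
    contacts: list[ContactEvent] = []
    for organ in anatomy.organs:
        if organ.spheres is not None:
            centers = organ.spheres[:, :3]
            radii = organ.spheres[:, 3]
            d = np.linalg.norm(P[:, None, :] - centers[None, :, :], axis=2) - radii[None, :]
            inside = np.any(d < 0.0, axis=1)
        elif organ.mesh is not None:
            from .collision import build_bvh, point_in_mesh

            tree = build_bvh(organ.mesh)
            inside = np.array([point_in_mesh(organ.mesh, p, tree=tree) for p in P])
        else:  # pragma: no cover
            continue
        # debounce: one event per contiguous run of contact
        starts = np.nonzero(inside & ~np.concatenate(([False], inside[:-1])))[0]
        for i in starts:
            contacts.append(
                ContactEvent(t=float(tv[i]), organ=organ.name, position=P[i].copy(),
                             forbidden=organ.forbidden)
            )
            sample_events[i].append(f"contact:{organ.name}")
    contacts.sort(key=lambda c: c.t)

    f_tot = f_ful + f_spr + f_dmp + f_frc
    return SimResult(
        t=tv, f_total=f_tot, f_fulcrum=f_ful, f_axial_spring=f_spr,
        f_damping=f_dmp, f_friction=f_frc, layer=labels,
        sample_events=sample_events, pops=pops, contacts=contacts,
        depth=depths, insertion_point=r,
    )
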