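"""Layered abdominal-wall model and forbidden-organ geometry.

The simulator works in a local *skin frame*: a right-handed, millimetre
coordinate system whose origin sits at the intended insertion site on the
skin, whose x-y plane is the skin tangent plane and whose +z axis is the
outward skin normal.  Insertion depth is measured along -z, so the wall
layers are slabs ``depth_start <= d < depth_end`` in normal depth ``d``.

Two kinds of geometry live here:

* the ordered stack of :class:`TissueLayer` slabs that the needle must
  traverse (skin, subcutaneous fat, linea alba, peritoneum by default),
  each carrying the dimensionless 0-1 haptic parameters (stiffness,
  damping, static/dynamic friction, pop-through) that the force model in
  :mod:`vnsim.haptics` maps to physical units;
* :class:`Organ` obstacles (vessels, bowel, pancreas, lateral peritoneum)
  placed below or lateral to the wall, contact with which counts as a
  mistake during scoring.

The default haptic parameter table reproduces the expert-tuned values for
each tissue model; :func:`generate_anatomy` builds a deterministic
synthetic anatomy around those values in place of a patient-specific mesh
set.
"""

from __future__ import annotations

import enum
import io
import os
from dataclasses import dataclass, field, replace

import numpy as np
import trimesh
import yaml

__all__ = [
    "TissueLayer",
    "Organ",
    "SkinFrame",
    "SceneState",
    "Anatomy",
    "ConfigurationError",
    "MeshFormatError",
    "default_tissue_table",
    "default_wall_thicknesses",
    "generate_anatomy",
    "read_mesh",
    "write_mesh",
    "load_anatomy_config",
    "dump_anatomy_config",
]


class ConfigurationError(ValueError):
    """Raised for invalid layer stacks, organ placements or parameter ranges."""


class MeshFormatError(ValueError):
    """Raised when a mesh file cannot be read or is structurally degenerate."""


_UNIT_PARAMS = ("stiffness", "damping", "static_friction", "dynamic_friction", "pop_through")


@dataclass(frozen=True)
class TissueLayer:
    """One abdominal-wall layer (a slab in normal depth) with haptic parameters.

    All haptic parameters are dimensionless in [0, 1]; the mapping to
    newtons / newton-seconds lives in :class:`vnsim.haptics.HapticConfig`.
    ``pop_through == 0`` means the layer presents no membrane at its entry
    surface (free traversal of its bulk).  ``distinct_pop`` marks the
    membranes whose rupture counts as one of the two clinical "pops"
    (linea alba and peritoneum); skin puncture is logged as an event but
    not counted among the pops.
    """

    name: str
    depth_start: float  # mm along the insertion normal
    depth_end: float  # mm
    stiffness: float = 0.0
    damping: float = 0.0
    static_friction: float = 0.0
    dynamic_friction: float = 0.0
    pop_through: float = 0.0
    distinct_pop: bool = False

    def __post_init__(self) -> None:
        if not self.depth_start < self.depth_end:
            raise ConfigurationError(
                f"layer {self.name!r}: depth_start ({self.depth_start}) must be "
                f"< depth_end ({self.depth_end})"
            )
        for p in _UNIT_PARAMS:
            v = getattr(self, p)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"layer {self.name!r}: {p}={v} outside [0, 1]")

    @property
    def thickness(self) -> float:
        return self.depth_end - self.depth_start

    def contains(self, depth: float) -> bool:
        return self.depth_start <= depth < self.depth_end


@dataclass
class Organ:
    """An organ obstacle: a set of analytic spheres and/or a triangle mesh.

    ``spheres`` is an (n, 4) array of (cx, cy, cz, radius) in skin-frame
    millimetres.  ``forbidden`` organs count toward the mistake tally when
    the needle tip contacts them.  ``deformable`` organs are contact-tested
    against a sphere-fill approximation rather than the rigid surface.
    """

    name: str
    spheres: np.ndarray | None = None
    mesh: trimesh.Trimesh | None = None
    forbidden: bool = True
    deformable: bool = False

    def __post_init__(self) -> None:
        if self.spheres is not None:
            self.spheres = np.atleast_2d(np.asarray(self.spheres, dtype=float))
            if self.spheres.shape[1] != 4:
                raise ConfigurationError(
                    f"organ {self.name!r}: spheres must be (n, 4) center+radius"
                )
            if np.any(self.spheres[:, 3] <= 0):
                raise ConfigurationError(f"organ {self.name!r}: sphere radii must be > 0")
        if self.spheres is None and self.mesh is None:
            raise ConfigurationError(f"organ {self.name!r}: needs spheres or a mesh")

    def distance(self, point: np.ndarray) -> float:
        """Signed distance from ``point`` to the organ surface (negative inside)."""
        d = np.inf
        if self.spheres is not None:
            centers = self.spheres[:, :3]
            radii = self.spheres[:, 3]
            d = float(np.min(np.linalg.norm(centers - point, axis=1) - radii))
        if self.mesh is not None:
            from .collision import MeshSurface  # local import: avoid module cycle

            d = min(d, MeshSurface(self.mesh).signed_distance(point))
        return d

    def contains(self, point: np.ndarray) -> bool:
        return self.distance(np.asarray(point, dtype=float)) < 0.0


@dataclass(frozen=True)
class SkinFrame:
    """Origin + orthonormal basis (tangent x, tangent y, outward normal z)."""

    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    x_axis: tuple[float, float, float] = (1.0, 0.0, 0.0)
    y_axis: tuple[float, float, float] = (0.0, 1.0, 0.0)
    normal: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        basis = np.array([self.x_axis, self.y_axis, self.normal], dtype=float)
        if not np.allclose(basis @ basis.T, np.eye(3), atol=1e-9):
            raise ConfigurationError("skin frame basis is not orthonormal to 1e-9")

    @property
    def basis(self) -> np.ndarray:
        return np.array([self.x_axis, self.y_axis, self.normal], dtype=float)

    def depth_of(self, point: np.ndarray) -> float:
        """Normal penetration depth of ``point`` (positive below the skin)."""
        rel = np.asarray(point, dtype=float) - np.asarray(self.origin)
        return -float(np.dot(rel, self.normal))


class SceneState(enum.IntEnum):
    """Preliminary-step bookkeeping: patient tilted, skin pinched/clamped, incised.

    Pure state flags gating the "preliminary steps completed" check in
    scoring; transitions only move forward and none alters the physics.
    """

    HORIZONTAL_TILTED = 1
    PINCHED_CLAMPED = 2
    INCISED = 3


@dataclass
class Anatomy:
    """A layer stack + organ set + skin frame: everything the simulator needs."""

    layers: list[TissueLayer]
    organs: list[Organ] = field(default_factory=list)
    skin_frame: SkinFrame = field(default_factory=SkinFrame)
    scene_state: SceneState = SceneState.HORIZONTAL_TILTED

    def __post_init__(self) -> None:
        if not self.layers:
            raise ConfigurationError("anatomy needs at least one wall layer")
        if abs(self.layers[0].depth_start) > 1e-12:
            raise ConfigurationError("first layer must start at depth 0 (skin surface)")
        for a, b in zip(self.layers, self.layers[1:]):
            if abs(a.depth_end - b.depth_start) > 1e-9:
                raise ConfigurationError(
                    f"layers {a.name!r} and {b.name!r} are not contiguous "
                    f"({a.depth_end} != {b.depth_start})"
                )

    @property
    def total_thickness(self) -> float:
        return self.layers[-1].depth_end

    def layer_at(self, depth: float) -> TissueLayer | None:
        """The unique layer containing ``depth``, or None outside the stack."""
        if depth < 0.0 or depth >= self.total_thickness:
            return None
        for layer in self.layers:
            if layer.contains(depth):
                return layer
        return None  # unreachable for a contiguous stack

    def advance_scene(self) -> None:
        if self.scene_state < SceneState.INCISED:
            self.scene_state = SceneState(self.scene_state + 1)

    @property
    def preliminary_steps_done(self) -> bool:
        return self.scene_state == SceneState.INCISED


# Expert-tuned default haptic parameters per tissue model
# (stiffness, damping, friction, pop-through), all dimensionless 0-1.
# The single friction value populates both static and dynamic friction.
_DEFAULT_TABLE: dict[str, tuple[float, float, float, float]] = {
    "bowel": (0.02, 0.0, 0.0, 0.01),
    "linea_alba": (0.5, 0.1, 0.1, 0.02),
    "pancreas": (0.1, 0.0, 0.0, 0.05),
    "peritoneum": (0.2, 0.05, 0.35, 0.05),
    "skin": (0.4, 0.1, 0.0, 0.05),
    "subcutaneous_fat": (0.0, 0.0, 0.0, 0.0),
    "vasculature": (0.2, 0.0, 0.0, 0.2),
}

# Wall layers in traversal order with synthetic default thicknesses (mm).
# The source patient model's thicknesses are not published; these are
# representative adult peri-umbilical values and fully configurable.
_DEFAULT_WALL_ORDER = ("skin", "subcutaneous_fat", "linea_alba", "peritoneum")
_DEFAULT_THICKNESS = {"skin": 3.0, "subcutaneous_fat": 20.0, "linea_alba": 2.0, "peritoneum": 1.0}
_DISTINCT_POPS = frozenset({"linea_alba", "peritoneum"})


def default_tissue_table() -> list[TissueLayer]:
    """The seven expert-tuned tissue entries as :class:`TissueLayer` templates.

    Entries are returned alphabetically by model name with placeholder unit
    depth extents (0-1 mm); wall-building code re-slabs them.  Static and
    dynamic friction both carry the single tuned friction value.
    """
    out = []
    for name in sorted(_DEFAULT_TABLE):
        s, d, f, p = _DEFAULT_TABLE[name]
        out.append(
            TissueLayer(
                name=name,
                depth_start=0.0,
                depth_end=1.0,
                stiffness=s,
                damping=d,
                static_friction=f,
                dynamic_friction=f,
                pop_through=p,
                distinct_pop=name in _DISTINCT_POPS,
            )
        )
    return out


def default_wall_thicknesses() -> dict[str, float]:
    return dict(_DEFAULT_THICKNESS)


def _default_organ_layout(wall_depth: float, corridor_radius: float, rng: np.random.Generator):
    """Forbidden organs below the wall / lateral to the insertion corridor.

    Bowel loops sit in the cavity along the nominal 45-degree insertion
    line (direction (0, 1, -1) from the entry point), so an insertion
    driven well past the peritoneum strikes them while a correctly
    stopped one does not.  Vessels and pancreas lie retroperitoneally
    (deeper); the lateral peritoneum flanks the corridor at wall depth.
    Placement is jittered deterministically per seed within bounds that
    keep every organ's nearest point strictly below ``wall_depth`` or
    laterally outside the corridor.
    """
    jit = lambda s: float(rng.uniform(-s, s))  # noqa: E731
    z0 = -wall_depth
    organs = [
        # bowel loops along the nominal insertion line, ~16 mm past the wall
        Organ(
            name="bowel",
            spheres=np.array(
                [
                    [jit(2), 31.0 + jit(2), -45.0 + jit(1), 10.0],
                    [jit(2), 42.0 + jit(2), -42.0 + jit(1), 10.0],
                    [jit(2), 56.0 + jit(2), -46.0 + jit(1), 10.0],
                ]
            ),
            deformable=True,
        ),
        # great vessels: a chain of small spheres deep on the midline
        Organ(
            name="vasculature",
            spheres=np.array(
                [[jit(1), -20.0 + 10.0 * i, -70.0 + jit(1), 5.0] for i in range(5)]
            ),
        ),
        Organ(
            name="pancreas",
            spheres=np.array([[jit(2), 28.0 + jit(2), -58.0 + jit(1), 9.0]]),
        ),
        Organ(
            name="colon",
            spheres=np.array([[34.0 + jit(2), 10.0 + jit(2), z0 - 20.0, 10.0]]),
            deformable=True,
        ),
        # lateral peritoneum: spheres flanking the corridor at wall depth
        Organ(
            name="lateral_peritoneum",
            spheres=np.array(
                [
                    [corridor_radius + 16.0, jit(2), z0 - 4.0, 10.0],
                    [-(corridor_radius + 16.0), jit(2), z0 - 4.0, 10.0],
                ]
            ),
        ),
    ]
    return organs


def generate_anatomy(
    layer_thicknesses: dict[str, float] | None = None,
    organ_layout: str | list[Organ] = "default",
    seed: int = 0,
    corridor_radius: float = 12.0,
) -> Anatomy:
    """Build a deterministic synthetic anatomy.

    Parameters
    ----------
    layer_thicknesses
        Mapping wall-layer name -> thickness in mm, in traversal order
        (insertion-order of the dict is honoured).  Defaults to the
        skin / fat / linea alba / peritoneum stack.
    organ_layout
        ``"default"`` for the built-in forbidden-organ set, ``"none"`` for
        a wall-only anatomy, or an explicit list of :class:`Organ`.
    seed
        Seeds the placement jitter; identical arguments give bitwise
        identical anatomies.
    corridor_radius
        Radius (mm) of the insertion corridor around the skin-frame z axis
        that organs must not intrude into above the wall's bottom.
    """
    thicknesses = dict(layer_thicknesses) if layer_thicknesses else dict(_DEFAULT_THICKNESS)
    if any(t <= 0 for t in thicknesses.values()):
        raise ConfigurationError("layer thicknesses must be positive")
    table = {l.name: l for l in default_tissue_table()}
    layers: list[TissueLayer] = []
    d = 0.0
    for name, t in thicknesses.items():
        template = table.get(name)
        if template is None:
            template = TissueLayer(name=name, depth_start=0.0, depth_end=1.0)
        layers.append(replace(template, depth_start=d, depth_end=d + t))
        d += t

    rng = np.random.default_rng(seed)
    if organ_layout == "default":
        organs = _default_organ_layout(d, corridor_radius, rng)
    elif organ_layout == "none":
        organs = []
    else:
        organs = list(organ_layout)

    anatomy = Anatomy(layers=layers, organs=organs)
    _check_organ_clearance(anatomy, corridor_radius)
    return anatomy


def _check_organ_clearance(anatomy: Anatomy, corridor_radius: float) -> None:
    """Every forbidden organ must sit below the wall or lateral to the corridor."""
    wall_depth = anatomy.total_thickness
    for organ in anatomy.organs:
        if not organ.forbidden or organ.spheres is None:
            continue
        for cx, cy, cz, r in organ.spheres:
            top = cz + r  # highest point, skin frame z
            lateral = np.hypot(cx, cy) - r  # nearest lateral approach to the axis
            if top > -wall_depth + 1e-9 and lateral < corridor_radius - 1e-9:
                raise ConfigurationError(
                    f"organ {organ.name!r} intrudes into the wall corridor "
                    f"(sphere at ({cx:.1f},{cy:.1f},{cz:.1f}) r={r:.1f})"
                )


# ---------------------------------------------------------------------------
# Mesh I/O (OBJ / ASCII+binary STL) via trimesh


def read_mesh(path: str | os.PathLike) -> trimesh.Trimesh:
    """Read an OBJ or STL triangle mesh (mm units assumed).

    Non-manifold meshes load fine; check ``mesh.is_watertight`` /
    ``mesh.is_winding_consistent`` for validity before volumetric use.
    """
    path = os.fspath(path)
    ext = os.path.splitext(path)[1].lower().lstrip(".")
    if ext not in ("obj", "stl"):
        raise MeshFormatError(f"{path}: unsupported mesh format {ext!r} (need obj/stl)")
    try:
        mesh = trimesh.load(path, file_type=ext, force="mesh", process=False)
    except Exception as exc:  # pragma: no cover - exact message varies by backend
        raise MeshFormatError(f"{path}: unreadable mesh file ({exc})") from exc
    if not isinstance(mesh, trimesh.Trimesh) or len(mesh.faces) == 0:
        raise MeshFormatError(f"{path}: no triangles found")
    return mesh


def write_mesh(mesh: trimesh.Trimesh, path: str | os.PathLike) -> None:
    """Write a mesh as OBJ or STL, chosen by file extension."""
    path = os.fspath(path)
    ext = os.path.splitext(path)[1].lower().lstrip(".")
    if ext not in ("obj", "stl"):
        raise MeshFormatError(f"{path}: unsupported mesh format {ext!r} (need obj/stl)")
    mesh.export(path)


# ---------------------------------------------------------------------------
# Anatomy configuration (YAML/JSON-compatible dict schema)


def dump_anatomy_config(anatomy: Anatomy) -> dict:
    """Serialize an anatomy to a plain dict (YAML/JSON-safe)."""
    return {
        "layers": [
            {
                "name": l.name,
                "depth_start": l.depth_start,
                "depth_end": l.depth_end,
                "stiffness": l.stiffness,
                "damping": l.damping,
                "static_friction": l.static_friction,
                "dynamic_friction": l.dynamic_friction,
                "pop_through": l.pop_through,
                "distinct_pop": l.distinct_pop,
            }
            for l in anatomy.layers
        ],
        "organs": [
            {
                "name": o.name,
                "spheres": None if o.spheres is None else o.spheres.tolist(),
                "forbidden": o.forbidden,
                "deformable": o.deformable,
            }
            for o in anatomy.organs
            if o.mesh is None
        ],
        "skin_frame": {
            "origin": list(anatomy.skin_frame.origin),
            "x_axis": list(anatomy.skin_frame.x_axis),
            "y_axis": list(anatomy.skin_frame.y_axis),
            "normal": list(anatomy.skin_frame.normal),
        },
        "scene_state": anatomy.scene_state.name.lower(),
    }


def load_anatomy_config(source: str | os.PathLike | io.TextIOBase | dict) -> Anatomy:
    """Build an Anatomy from a YAML file/stream or an already-parsed dict."""
    if isinstance(source, dict):
        cfg = source
    elif isinstance(source, io.TextIOBase):
        cfg = yaml.safe_load(source)
    else:
        with open(source) as fh:
            cfg = yaml.safe_load(fh)
    layers = [TissueLayer(**entry) for entry in cfg["layers"]]
    organs = [
        Organ(
            name=e["name"],
            spheres=np.asarray(e["spheres"], dtype=float) if e.get("spheres") else None,
            forbidden=e.get("forbidden", True),
            deformable=e.get("deformable", False),
        )
        for e in cfg.get("organs", [])
    ]
    sf = cfg.get("skin_frame", {})
    frame = SkinFrame(
        origin=tuple(sf.get("origin", (0, 0, 0))),
        x_axis=tuple(sf.get("x_axis", (1, 0, 0))),
        y_axis=tuple(sf.get("y_axis", (0, 1, 0))),
        normal=tuple(sf.get("normal", (0, 0, 1))),
    )
    state = SceneState[cfg.get("scene_state", "horizontal_tilted").upper()]
    return Anatomy(layers=layers, organs=organs, skin_frame=frame, scene_state=state)
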