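"""Contact primitives for the haptic loop.

Proxy (god-object) stepping against analytic and triangle-mesh surfaces,
an axis-aligned bounding-box tree for triangle candidate culling, a
ray-crossing point-in-mesh test, and a sphere-fill volume approximation
used for deformable-tagged organs, where contact is tested against the
filling spheres rather than the rigid surface.

Conventions: positions in mm.  Surfaces separate an "outside" (where the
device normally lives) from an "inside"; penetration depth is the distance
from the device point to the proxy when the device is inside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import trimesh

__all__ = [
    "PlaneSurface",
    "SphereSurface",
    "MeshSurface",
    "proxy_step",
    "AABBTree",
    "build_bvh",
    "point_in_mesh",
    "fill_spheres",
    "OpenMeshError",
]


class OpenMeshError(ValueError):
    """Raised when a volumetric operation is asked of an open (non-watertight) mesh."""


@dataclass(frozen=True)
class PlaneSurface:
    """Half-space surface: inside is where dot(p - point, normal) < 0."""

    point: tuple[float, float, float]
    normal: tuple[float, float, float]

    def signed_distance(self, p: np.ndarray) -> float:
        n = np.asarray(self.normal, dtype=float)
        n = n / np.linalg.norm(n)
        return float(np.dot(np.asarray(p, float) - np.asarray(self.point, float), n))

    def closest_point(self, p: np.ndarray) -> np.ndarray:
        n = np.asarray(self.normal, dtype=float)
        n = n / np.linalg.norm(n)
        return np.asarray(p, float) - self.signed_distance(p) * n


@dataclass(frozen=True)
class SphereSurface:
    """Sphere surface: inside is the ball of the given radius."""

    center: tuple[float, float, float]
    radius: float

    def signed_distance(self, p: np.ndarray) -> float:
        return float(np.linalg.norm(np.asarray(p, float) - np.asarray(self.center, float))
                     - self.radius)

    def closest_point(self, p: np.ndarray) -> np.ndarray:
        c = np.asarray(self.center, float)
        v = np.asarray(p, float) - c
        n = np.linalg.norm(v)
        if n < 1e-12:
            # degenerate: device at the center; pick +z arbitrarily but stably
            v = np.array([0.0, 0.0, 1.0])
            n = 1.0
        return c + v * (self.radius / n)


class MeshSurface:
    """Triangle-mesh surface with BVH-accelerated closest-point queries."""

    def __init__(self, mesh: trimesh.Trimesh):
        self.mesh = mesh
        self.tree = build_bvh(mesh)
        if not (mesh.is_watertight and mesh.is_winding_consistent):
            warnings.warn(
                "mesh surface is not manifold; falling back to nearest-triangle "
                "projection with outside-normal sign heuristic",
                stacklevel=2,
            )
            self._manifold = False
        else:
            self._manifold = True

    def signed_distance(self, p: np.ndarray) -> float:
        cp = self.closest_point(p)
        d = float(np.linalg.norm(np.asarray(p, float) - cp))
        if self._manifold and point_in_mesh(self.mesh, p, tree=self.tree):
            return -d
        return d

    def closest_point(self, p: np.ndarray) -> np.ndarray:
        p = np.asarray(p, dtype=float)
        idx = self.tree.closest_candidates(p)
        tris = self.mesh.triangles[idx]
        pts = _closest_point_on_triangles(tris, p)
        best = int(np.argmin(np.linalg.norm(pts - p, axis=1)))
        return pts[best]


def proxy_step(surface, device_pos, proxy_pos, popped: bool):
    """One proxy (god-object) update.

    If the device is outside the surface (or the membrane has popped),
    the proxy snaps to the device and penetration is 0.  If the device
    penetrates an un-popped surface, the proxy is the closest point on the
    surface and the penetration depth is the proxy-device distance.

    Returns ``(new_proxy, penetration_mm)``.
    """
    device = np.asarray(device_pos, dtype=float)
    if popped or surface.signed_distance(device) >= 0.0:
        return device.copy(), 0.0
    proxy = surface.closest_point(device)
    return proxy, float(np.linalg.norm(proxy - device))


# ---------------------------------------------------------------------------
# AABB tree over triangles


class AABBTree:
    """Median-split axis-aligned bounding-box tree over a triangle soup.

    Queries return candidate triangle indices — always a superset of the
    triangles actually within reach, with brute-force equivalence on the
    final exact tests.
    """

    __slots__ = ("lo", "hi", "_nodes", "n_triangles")

    def __init__(self, triangles: np.ndarray, leaf_size: int = 8):
        triangles = np.asarray(triangles, dtype=float)
        self.n_triangles = len(triangles)
        if self.n_triangles == 0:
            self.lo = self.hi = None
            self._nodes = []
            return
        self.lo = triangles.min(axis=1)  # (n, 3) per-triangle box
        self.hi = triangles.max(axis=1)
        # nodes: (box_lo, box_hi, left, right, tri_indices_or_None)
        self._nodes: list[tuple] = []
        self._build(np.arange(self.n_triangles), leaf_size)

    def _build(self, idx: np.ndarray, leaf_size: int) -> int:
        lo = self.lo[idx].min(axis=0)
        hi = self.hi[idx].max(axis=0)
        node_id = len(self._nodes)
        self._nodes.append(None)  # reserve
        if len(idx) <= leaf_size:
            self._nodes[node_id] = (lo, hi, -1, -1, idx)
            return node_id
        centers = 0.5 * (self.lo[idx] + self.hi[idx])
        axis = int(np.argmax(hi - lo))
        order = np.argsort(centers[:, axis], kind="stable")
        half = len(idx) // 2
        left = self._build(idx[order[:half]], leaf_size)
        right = self._build(idx[order[half:]], leaf_size)
        self._nodes[node_id] = (lo, hi, left, right, None)
        return node_id

    def query_aabb(self, box_lo, box_hi) -> np.ndarray:
        """Triangle indices whose boxes overlap the query box."""
        if self.n_triangles == 0:
            return np.empty(0, dtype=int)
        box_lo = np.asarray(box_lo, float)
        box_hi = np.asarray(box_hi, float)
        out: list[np.ndarray] = []
        stack = [0]
        while stack:
            lo, hi, left, right, leaf = self._nodes[stack.pop()]
            if np.any(box_hi < lo) or np.any(box_lo > hi):
                continue
            if leaf is not None:
                keep = ~(
                    np.any(self.hi[leaf] < box_lo, axis=1)
                    | np.any(self.lo[leaf] > box_hi, axis=1)
                )
                if keep.any():
                    out.append(leaf[keep])
            else:
                stack.append(left)
                stack.append(right)
        if not out:
            return np.empty(0, dtype=int)
        return np.sort(np.concatenate(out))

    def query_point(self, point, radius: float = 0.0) -> np.ndarray:
        p = np.asarray(point, dtype=float)
        return self.query_aabb(p - radius, p + radius)

    def query_segment(self, a, b, radius: float = 0.0) -> np.ndarray:
        a = np.asarray(a, float)
        b = np.asarray(b, float)
        return self.query_aabb(np.minimum(a, b) - radius, np.maximum(a, b) + radius)

    def closest_candidates(self, point) -> np.ndarray:
        """Triangle indices guaranteed to contain the globally closest triangle.

        Expands a point query radius until non-empty, then re-queries at a
        radius covering the current best upper bound.
        """
        if self.n_triangles == 0:
            return np.empty(0, dtype=int)
        p = np.asarray(point, dtype=float)
        root_lo, root_hi = self._nodes[0][0], self._nodes[0][1]
        scale = float(np.max(root_hi - root_lo)) or 1.0
        r = 0.05 * scale
        idx = self.query_point(p, r)
        while len(idx) == 0:
            r *= 2.0
            idx = self.query_point(p, r)
        # upper bound: farthest corner of the nearest candidate's box
        d_hi = np.minimum(
            np.linalg.norm(self.lo[idx] - p, axis=1),
            np.linalg.norm(self.hi[idx] - p, axis=1),
        ).min() + np.linalg.norm(self.hi[idx[0]] - self.lo[idx[0]])
        return self.query_point(p, float(max(r, d_hi)))


def build_bvh(mesh: trimesh.Trimesh | np.ndarray) -> AABBTree:
    """Bounding-volume hierarchy over a mesh's triangles (empty mesh -> empty tree)."""
    tris = mesh.triangles if isinstance(mesh, trimesh.Trimesh) else np.asarray(mesh, float)
    if len(tris) == 0:
        return AABBTree(np.empty((0, 3, 3)))
    return AABBTree(tris)


def _closest_point_on_triangles(tris: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Closest point to ``p`` on each triangle of ``tris`` (n, 3, 3) — Ericson's method."""
    a, b, c = tris[:, 0], tris[:, 1], tris[:, 2]
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    out = np.empty_like(a)
    done = np.zeros(len(tris), dtype=bool)

    m = (d1 <= 0) & (d2 <= 0)  # vertex a
    out[m] = a[m]
    done |= m
    m = ~done & (d3 >= 0) & (d4 <= d3)  # vertex b
    out[m] = b[m]
    done |= m
    m = ~done & (d6 >= 0) & (d5 <= d6)  # vertex c
    out[m] = c[m]
    done |= m

    vc = d1 * d4 - d3 * d2
    m = ~done & (vc <= 0) & (d1 >= 0) & (d3 <= 0)  # edge ab
    with np.errstate(invalid="ignore", divide="ignore"):
        v = np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0)
    out[m] = a[m] + v[m, None] * ab[m]
    done |= m

    vb = d5 * d2 - d1 * d6
    m = ~done & (vb <= 0) & (d2 >= 0) & (d6 <= 0)  # edge ac
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0)
    out[m] = a[m] + w[m, None] * ac[m]
    done |= m

    va = d3 * d6 - d5 * d4
    m = ~done & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)  # edge bc
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where((d4 - d3) + (d5 - d6) != 0, (d4 - d3) / ((d4 - d3) + (d5 - d6)), 0.0)
    out[m] = b[m] + w[m, None] * (c[m] - b[m])
    done |= m

    m = ~done  # interior
    denom = va + vb + vc
    with np.errstate(invalid="ignore", divide="ignore"):
        v = np.where(denom != 0, vb / denom, 1 / 3)
        w = np.where(denom != 0, vc / denom, 1 / 3)
    out[m] = a[m] + v[m, None] * ab[m] + w[m, None] * ac[m]
    return out


# ---------------------------------------------------------------------------
# Point-in-mesh by ray crossing


def point_in_mesh(mesh: trimesh.Trimesh, point, tree: AABBTree | None = None) -> bool:
    """Ray-crossing parity test for a closed mesh.

    Casts a ray in a fixed slightly-irrational direction (robust against
    axis-aligned edge grazing) and counts triangle crossings; odd = inside.
    """
    p = np.asarray(point, dtype=float)
    direction = np.array([0.5773502691896258, 0.211324865405187, 0.7886751345948129])
    direction /= np.linalg.norm(direction)
    tris = mesh.triangles
    if tree is not None:
        span = float(np.linalg.norm(mesh.bounds[1] - mesh.bounds[0])) + 1.0
        idx = tree.query_segment(p, p + direction * span)
        tris = tris[idx]
    return _count_ray_hits(tris, p, direction) % 2 == 1


def _count_ray_hits(tris: np.ndarray, origin: np.ndarray, direction: np.ndarray) -> int:
    """Möller-Trumbore ray-triangle crossings (t > 0), vectorised."""
    if len(tris) == 0:
        return 0
    v0, v1, v2 = tris[:, 0], tris[:, 1], tris[:, 2]
    e1 = v1 - v0
    e2 = v2 - v0
    h = np.cross(direction, e2)
    det = np.einsum("ij,ij->i", e1, h)
    ok = np.abs(det) > 1e-12
    inv = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
    s = origin - v0
    u = np.einsum("ij,ij->i", s, h) * inv
    q = np.cross(s, e1)
    v = np.einsum("ij,ij->i", q, np.broadcast_to(direction, s.shape)) * inv
    t = np.einsum("ij,ij->i", e2, q) * inv
    hits = ok & (u >= 0) & (v >= 0) & (u + v <= 1) & (t > 1e-9)
    return int(np.count_nonzero(hits))


# ---------------------------------------------------------------------------
# Sphere-fill volume approximation for deformable organs


def fill_spheres(mesh: trimesh.Trimesh, n_spheres: int, seed: int = 0) -> np.ndarray:
    """Approximate a closed mesh's volume with interior spheres.

    Returns an (n_spheres, 4) array of (cx, cy, cz, r).  Centers are
    chosen by farthest-point selection among interior samples; each radius
    is the center's distance to the mesh surface, so every sphere lies
    fully inside.  Raises :class:`OpenMeshError` for open meshes (use
    rigid contact for those).
    """
    if not mesh.is_watertight:
        raise OpenMeshError(
            "sphere filling needs a closed mesh; use rigid mesh contact instead"
        )
    if n_spheres < 1:
        raise ValueError("n_spheres must be >= 1")
    tree = build_bvh(mesh)
    rng = np.random.default_rng(seed)
    lo, hi = mesh.bounds

    n_target = max(200, 40 * n_spheres)
    samples = []
    for _ in range(200):  # rejection-sample interior points
        pts = rng.uniform(lo, hi, size=(4 * n_target, 3))
        inside = [p for p in pts if point_in_mesh(mesh, p, tree=tree)]
        samples.extend(inside)
        if len(samples) >= n_target:
            break
    if not samples:
        raise OpenMeshError("could not sample interior points (degenerate volume)")
    samples = np.asarray(samples[:n_target])

    centroid = samples.mean(axis=0)
    if point_in_mesh(mesh, centroid, tree=tree):
        centers = [centroid]
    else:
        centers = [samples[0]]
    while len(centers) < n_spheres:
        d = np.min(
            np.linalg.norm(samples[:, None, :] - np.asarray(centers)[None, :, :], axis=2),
            axis=1,
        )
        centers.append(samples[int(np.argmax(d))])

    surface = MeshSurface(mesh)
    out = np.empty((n_spheres, 4))
    for i, c in enumerate(centers):
        out[i, :3] = c
        out[i, 3] = max(abs(surface.signed_distance(c)), 1e-6)
    return out
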