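"""Exact computational geometry shared by all analysis stages.

All coordinates are in nanometers. 3D scenes use a right-handed frame with
the presynaptic membrane reference plane at z = 0 and the cytoplasm at
z > 0, so "depth into the bouton" is simply the z coordinate.

The central primitive is the shortest Euclidean distance from a point (a
vesicle center) to a triangulated surface (a segmented active-zone patch),
evaluated exactly for the polyhedral surface — interior, edge and vertex
cases included — via a vectorised closest-point-on-triangle computation.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, NamedTuple

import numpy as np
import trimesh

__all__ = [
    "TriangleMesh",
    "PolyLine2D",
    "SphereModel",
    "SphereFit",
    "VesicleDistance",
    "point_to_mesh_distance",
    "points_to_mesh_distance",
    "vesicle_to_surface_distance",
    "mesh_area",
    "fit_sphere",
    "spherical_cap_area",
    "point_to_polyline_distance",
    "point_to_segments_distance",
    "point_to_disk_distance",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class TriangleMesh:
    """A triangulated surface with an optional per-face validity flag.

    ``face_valid`` marks faces that survived the missing-wedge occlusion
    model (``False`` = obscured).  Zero-area faces are dropped at
    construction so downstream area and distance computations never see
    degenerate triangles.
    """

    vertices: np.ndarray  # (V, 3) float, nm
    faces: np.ndarray  # (F, 3) int
    face_valid: np.ndarray | None = None  # (F,) bool

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (V, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (F, 3)")
        if self.faces.size and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise ValueError("face index out of range")
        if self.face_valid is not None:
            self.face_valid = np.asarray(self.face_valid, dtype=bool)
            if self.face_valid.shape != (len(self.faces),):
                raise ValueError("face_valid must have one flag per face")
        # drop zero-area faces
        areas = _triangle_areas(self.vertices[self.faces])
        keep = areas > 0.0
        if not keep.all():
            self.faces = self.faces[keep]
            if self.face_valid is not None:
                self.face_valid = self.face_valid[keep]
        if len(self.faces) == 0:
            raise ValueError("no surface")

    # -- derived geometry ---------------------------------------------------

    @property
    def triangles(self) -> np.ndarray:
        """(F, 3, 3) triangle vertex coordinates."""
        return self.vertices[self.faces]

    @property
    def face_areas(self) -> np.ndarray:
        return _triangle_areas(self.triangles)

    @property
    def face_normals(self) -> np.ndarray:
        tri = self.triangles
        n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        return n / np.linalg.norm(n, axis=1, keepdims=True)

    def valid_mask(self) -> np.ndarray:
        if self.face_valid is None:
            return np.ones(len(self.faces), dtype=bool)
        return self.face_valid

    def boundary_segments(self) -> np.ndarray:
        """(S, 2, 3) open-boundary edge segments (edges used by one face)."""
        edges = np.sort(
            self.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1
        )
        uniq, counts = np.unique(edges, axis=0, return_counts=True)
        border = uniq[counts == 1]
        return self.vertices[border]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "TriangleMesh":
        v = self.vertices @ np.asarray(rotation).T + np.asarray(translation)
        fv = None if self.face_valid is None else self.face_valid.copy()
        return TriangleMesh(v, self.faces.copy(), fv)

    # -- interchange --------------------------------------------------------

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices, faces=self.faces, process=False
        )

    @classmethod
    def from_trimesh(cls, mesh: trimesh.Trimesh, face_valid=None) -> "TriangleMesh":
        return cls(np.asarray(mesh.vertices), np.asarray(mesh.faces), face_valid)

    def save(self, path) -> None:
        """Write PLY/OBJ (format from the file suffix)."""
        self.to_trimesh().export(path)

    @classmethod
    def load(cls, path, face_valid=None) -> "TriangleMesh":
        m = trimesh.load_mesh(path, process=False)
        return cls.from_trimesh(m, face_valid)


@dataclasses.dataclass
class PolyLine2D:
    """An ordered open polyline tracing an AZ profile in a section plane."""

    points: np.ndarray  # (N, 2) nm

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be (N, 2)")
        if len(self.points) < 2:
            raise ValueError("polyline needs >= 2 points")
        seg = np.diff(self.points, axis=0)
        lengths = np.linalg.norm(seg, axis=1)
        if np.any(lengths == 0.0):
            raise ValueError("repeated consecutive points")

    @property
    def length(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())


@dataclasses.dataclass
class SphereModel:
    center: np.ndarray  # (3,) nm
    radius: float  # nm

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        self.radius = float(self.radius)
        if self.radius <= 0:
            raise ValueError("radius must be > 0")

    @property
    def diameter(self) -> float:
        return 2.0 * self.radius

    @property
    def surface_area(self) -> float:
        return 4.0 * np.pi * self.radius**2


class SphereFit(NamedTuple):
    sphere: SphereModel
    rms_residual: float


class VesicleDistance(NamedTuple):
    """Membrane-to-surface gap; ``raw`` keeps any negative interpenetration."""

    distance: float  # clamped at 0
    raw: float


# ---------------------------------------------------------------------------
# distance primitives
# ---------------------------------------------------------------------------


def _triangle_areas(tri: np.ndarray) -> np.ndarray:
    return 0.5 * np.linalg.norm(
        np.cross(tri[..., 1, :] - tri[..., 0, :], tri[..., 2, :] - tri[..., 0, :]),
        axis=-1,
    )


def closest_points_on_triangles(points: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Closest point on each triangle to each query point.

    points : (N, 3); tri : (M, 3, 3).  Returns (N, M, 3).  Standard
    barycentric-region case analysis (Voronoi regions of vertex / edge /
    face), vectorised over the full N x M grid.
    """
    a = tri[:, 0][None]  # (1, M, 3)
    b = tri[:, 1][None]
    c = tri[:, 2][None]
    p = points[:, None, :]  # (N, 1, 3)

    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("nmk,nmk->nm", np.broadcast_arrays(ab, ap)[0], ap)
    d2 = np.einsum("nmk,nmk->nm", np.broadcast_arrays(ac, ap)[0], ap)

    bp = p - b
    d3 = np.einsum("nmk,nmk->nm", np.broadcast_arrays(ab, bp)[0], bp)
    d4 = np.einsum("nmk,nmk->nm", np.broadcast_arrays(ac, bp)[0], bp)

    cp = p - c
    d5 = np.einsum("nmk,nmk->nm", np.broadcast_arrays(ab, cp)[0], cp)
    d6 = np.einsum("nmk,nmk->nm", np.broadcast_arrays(ac, cp)[0], cp)

    vc = d1 * d4 - d3 * d2
    vb = d5 * d2 - d1 * d6
    va = d3 * d6 - d5 * d4

    eps = 0.0
    n, m = d1.shape
    out = np.empty((n, m, 3))
    done = np.zeros((n, m), dtype=bool)

    # vertex A region
    mask = (d1 <= eps) & (d2 <= eps)
    out[mask] = np.broadcast_to(a, (n, m, 3))[mask]
    done |= mask

    # vertex B region
    mask = (~done) & (d3 >= -eps) & (d4 <= d3)
    out[mask] = np.broadcast_to(b, (n, m, 3))[mask]
    done |= mask

    # edge AB
    mask = (~done) & (vc <= eps) & (d1 >= -eps) & (d3 <= eps)
    if mask.any():
        with np.errstate(divide="ignore", invalid="ignore"):
            v = d1 / (d1 - d3)
        pt = a + np.nan_to_num(v)[..., None] * ab
        out[mask] = np.broadcast_to(pt, (n, m, 3))[mask]
        done |= mask

    # vertex C region
    mask = (~done) & (d6 >= -eps) & (d5 <= d6)
    out[mask] = np.broadcast_to(c, (n, m, 3))[mask]
    done |= mask

    # edge AC
    mask = (~done) & (vb <= eps) & (d2 >= -eps) & (d6 <= eps)
    if mask.any():
        with np.errstate(divide="ignore", invalid="ignore"):
            w = np.nan_to_num(d2 / (d2 - d6))
        pt = a + w[..., None] * ac
        out[mask] = np.broadcast_to(pt, (n, m, 3))[mask]
        done |= mask

    # edge BC
    mask = (~done) & (va <= eps) & ((d4 - d3) >= -eps) & ((d5 - d6) >= -eps)
    if mask.any():
        with np.errstate(divide="ignore", invalid="ignore"):
            w = np.nan_to_num((d4 - d3) / ((d4 - d3) + (d5 - d6)))
        pt = b + w[..., None] * (c - b)
        out[mask] = np.broadcast_to(pt, (n, m, 3))[mask]
        done |= mask

    # face interior
    mask = ~done
    if mask.any():
        denom = va + vb + vc
        v = vb / denom
        w = vc / denom
        pt = a + v[..., None] * ab + w[..., None] * ac
        out[mask] = np.broadcast_to(pt, (n, m, 3))[mask]
    return out


def points_to_mesh_distance(
    points: np.ndarray,
    mesh: TriangleMesh,
    valid_only: bool = True,
    chunk: int = 2_000_000,
) -> np.ndarray:
    """Minimum distance from each point to the (valid part of the) surface.

    Work is chunked so the N x M closest-point grid stays within memory for
    large meshes.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    tri = mesh.triangles
    if valid_only:
        tri = tri[mesh.valid_mask()]
    if len(tri) == 0:
        raise ValueError("no surface")
    n = len(points)
    best = np.empty(n)
    # conservative cull: a triangle can only beat the current bound if the
    # distance to its bounding sphere can; exactness is preserved
    centroids = tri.mean(axis=1)
    r_circ = np.linalg.norm(tri - centroids[:, None, :], axis=2).max(axis=1)
    for i, p in enumerate(points):
        cd = np.linalg.norm(centroids - p, axis=1)
        ub = float((cd + r_circ).min())
        cand = tri[cd - r_circ <= ub]
        cp = closest_points_on_triangles(p[None], cand)
        best[i] = float(np.linalg.norm(cp - p, axis=2).min())
    return best


def point_to_mesh_distance(p: np.ndarray, mesh: TriangleMesh, valid_only: bool = True) -> float:
    return float(points_to_mesh_distance(np.asarray(p, dtype=float)[None], mesh, valid_only)[0])


def vesicle_to_surface_distance(v: SphereModel, mesh: TriangleMesh) -> VesicleDistance:
    """Membrane-to-membrane gap between a spherical vesicle and a surface.

    Center-to-surface distance minus the vesicle radius.  Negative values
    (interpenetration from segmentation jitter) clamp to 0 — a vesicle
    touching the membrane has no measurable gap — while the raw signed
    value is retained for quality control.
    """
    raw = point_to_mesh_distance(v.center, mesh) - v.radius
    return VesicleDistance(max(raw, 0.0), raw)


def mesh_area(mesh: TriangleMesh, valid_only: bool = False) -> float:
    """Total triangle area; optionally only wedge-valid faces."""
    areas = mesh.face_areas
    if valid_only:
        areas = areas[mesh.valid_mask()]
    return float(areas.sum())


# ---------------------------------------------------------------------------
# sphere fitting and caps
# ---------------------------------------------------------------------------


def fit_sphere(points: np.ndarray) -> SphereFit:
    """Least-squares sphere through a 3D point cloud.

    Algebraic (Coope) linear solve followed by geometric Gauss-Newton
    refinement of sum((|p - c| - r)^2).  Used to complete membrane
    profiles obscured by the missing wedge.

    Raises ``ValueError("sphere underdetermined")`` for < 4 points or
    (near-)coplanar input, where infinitely many spheres fit.
    """
    pts = np.asarray(points, dtype=float)
    pts = pts.reshape(-1, 3)
    if len(pts) < 4:
        raise ValueError("sphere underdetermined")
    # work in a centered frame for conditioning
    mean = pts.mean(axis=0)
    q = pts - mean
    A = np.column_stack([2.0 * q, np.ones(len(q))])
    b = np.einsum("ij,ij->i", q, q)
    sol, _, rank, sv = np.linalg.lstsq(A, b, rcond=None)
    if rank < 4 or sv[-1] < 1e-9 * sv[0]:
        raise ValueError("sphere underdetermined")
    center = sol[:3]
    r2 = sol[3] + center @ center
    if r2 <= 0:
        raise ValueError("sphere underdetermined")
    radius = float(np.sqrt(r2))

    # Gauss-Newton on (c, r)
    c = center.copy()
    r = radius
    for _ in range(50):
        diff = q - c
        dist = np.linalg.norm(diff, axis=1)
        dist = np.maximum(dist, 1e-12)
        res = dist - r
        J = np.column_stack([-diff / dist[:, None], -np.ones(len(q))])
        step, *_ = np.linalg.lstsq(J, -res, rcond=None)
        c = c + step[:3]
        r = r + step[3]
        if np.linalg.norm(step) < 1e-12 * max(r, 1.0):
            break
    if r <= 0:
        raise ValueError("sphere underdetermined")
    diff = q - c
    res = np.linalg.norm(diff, axis=1) - r
    rms = float(np.sqrt(np.mean(res**2)))
    return SphereFit(SphereModel(c + mean, float(r)), rms)


def spherical_cap_area(base_radius: float, depth: float) -> float:
    """Lateral area of a spherical cap with base radius ``a`` and depth ``h``.

    Closed form pi * (a^2 + h^2); the hemisphere (a = h = R) gives 2 pi R^2.
    """
    a = float(base_radius)
    h = float(depth)
    if a < 0:
        raise ValueError("base radius must be >= 0")
    if h <= 0:
        raise ValueError("depth must be > 0")
    return np.pi * (a * a + h * h)


# ---------------------------------------------------------------------------
# 2D / analytic helpers
# ---------------------------------------------------------------------------


def point_to_segments_distance(p: np.ndarray, segments: np.ndarray) -> float:
    """Min distance from a point to a set of segments ((S, 2, D) endpoints)."""
    p = np.asarray(p, dtype=float)
    a = segments[:, 0]
    b = segments[:, 1]
    ab = b - a
    denom = np.einsum("ij,ij->i", ab, ab)
    t = np.clip(np.einsum("ij,ij->i", p - a, ab) / np.where(denom == 0, 1, denom), 0, 1)
    proj = a + t[:, None] * ab
    return float(np.linalg.norm(proj - p, axis=1).min())


def point_to_polyline_distance(p: np.ndarray, line: PolyLine2D) -> float:
    pts = line.points
    segs = np.stack([pts[:-1], pts[1:]], axis=1)
    return point_to_segments_distance(p, segs)


def point_to_disk_distance(
    p: np.ndarray, center: np.ndarray, normal: np.ndarray, radius: float
) -> float:
    """Exact distance from a point to a closed planar disk (analytic).

    Used by the synthetic generator to tabulate ground-truth vesicle
    distances independently of any meshing.
    """
    p = np.asarray(p, dtype=float)
    center = np.asarray(center, dtype=float)
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    d = p - center
    z = d @ n
    radial = d - z * n
    rho = np.linalg.norm(radial)
    if rho <= radius:
        return abs(float(z))
    return float(np.hypot(rho - radius, z))
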