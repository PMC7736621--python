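"""Morphometry of putative endocytic membrane invaginations (omega profiles).

For each pit the module measures, in the membrane reference frame
(membrane plane z = 0, invagination rising into z > 0):

* D — maximal diameter: the widest cross-section parallel to the membrane;
* I — maximal invagination depth: tip height above the membrane plane,
  i.e. along the membrane normal over the pore;
* P — minimal pore width: the narrowest cross-section at or below the
  widest one (the neck / opening);
* the D/P shape class, with a +/-0.05 tolerance band around D/P = 1 and
  a "near-budding" flag for D/P > 1.5 with a pore under 100 nm;
* the missing-wedge-completed surface area (valid faces plus the
  occluded part reconstructed on a least-squares sphere fit);
* SV-equivalents: area over the surface of a 46-nm sphere;
* peri-AZ (<= 200 nm from the AZ edge) versus distal zoning.

2D measurements run the same slab logic on section contours and are
flagged ``dimension="2D"``; they systematically underestimate D and I.
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .geometry import (
    TriangleMesh,
    fit_sphere,
    mesh_area,
    point_to_segments_distance,
)

__all__ = [
    "PitMeasurement",
    "PitCensus",
    "measure_pit",
    "measure_pit_2d",
    "classify_pit",
    "pit_surface_area",
    "sv_equivalents",
    "zone_pit",
    "filter_census",
]

MEAN_DOCKED_SV_DIAMETER_NM = 46.0
PERI_AZ_MAX_NM = 200.0
BUDDING_RATIO = 1.5
BUDDING_PORE_MAX_NM = 100.0
EQ1_TOLERANCE = 0.05

SHAPE_CLASSES = ("EQ1", "GT1_1p5", "R1p5_2", "GT2")


@dataclasses.dataclass
class PitMeasurement:
    pit_id: object
    D_nm: float
    I_nm: float
    P_nm: float
    dimension: str = "3D"
    ratio: float = math.nan
    shape_class: str = ""
    near_budding: bool = False
    area_nm2: float = math.nan
    sv_equivalents: float = math.nan
    az_edge_distance_nm: float = math.nan
    zone: str = ""
    coated: bool = False
    bouton_id: object = None
    midline_in_volume: bool = True
    fully_in_volume: bool = True


@dataclasses.dataclass
class PitCensus:
    """Per-bouton incidence of coated and non-coated invaginations."""

    per_bouton: pd.DataFrame  # bouton_id, n_coated, n_noncoated
    incidence_coated: float  # events / bouton
    incidence_noncoated: float
    n_boutons: int
    morphometry_ids: list  # pits eligible for D/I/P (midline in volume)
    area_ids: list  # pits eligible for surface area (fully in volume)


# ---------------------------------------------------------------------------
# core measurement
# ---------------------------------------------------------------------------


def _slab_widths(points: np.ndarray, heights: np.ndarray, slab: float):
    """Max lateral extent per height slab.

    ``points`` are lateral coordinates ((N, 2) in 3D, (N, 1) in 2D);
    returns (slab center heights, widths).
    """
    z0, z1 = heights.min(), heights.max()
    n = max(1, int(math.ceil((z1 - z0) / slab)))
    idx = np.clip(((heights - z0) / slab).astype(int), 0, n - 1)
    centers = z0 + (np.arange(n) + 0.5) * slab
    widths = np.full(n, np.nan)
    for b in range(n):
        pts = points[idx == b]
        if len(pts) < 2:
            continue
        widths[b] = _max_pairwise(pts)
    return centers, widths


def _max_pairwise(pts: np.ndarray) -> float:
    if pts.shape[1] == 1:
        return float(pts.max() - pts.min())
    if len(pts) > 10:
        try:
            hull = ConvexHull(pts)
            pts = pts[hull.vertices]
        except QhullError:
            pass
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
    return float(d.max())


def _measure(points_lateral, heights, edge_estimate, pit_id, dimension) -> PitMeasurement:
    if heights.min() > 2.0 * edge_estimate:
        raise ValueError("open surface without pore")
    slab = max(edge_estimate, 1e-6)
    centers, widths = _slab_widths(points_lateral, heights, slab)
    finite = np.isfinite(widths)
    if not finite.any():
        raise ValueError("open surface without pore")
    i_max = int(np.nanargmax(widths))
    D = float(widths[i_max])
    below = widths[: i_max + 1]
    P = float(np.nanmin(below))
    I = float(heights.max())
    return PitMeasurement(pit_id=pit_id, D_nm=D, I_nm=I, P_nm=P, dimension=dimension)


def _membrane_frame(membrane_origin, membrane_normal):
    n = np.asarray(membrane_normal, dtype=float)
    n = n / np.linalg.norm(n)
    # build an orthonormal lateral basis
    a = np.array([1.0, 0.0, 0.0])
    if abs(n @ a) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    u = np.cross(n, a)
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    return np.asarray(membrane_origin, dtype=float), u, v, n


def measure_pit(
    mesh: TriangleMesh,
    membrane_origin=(0.0, 0.0, 0.0),
    membrane_normal=(0.0, 0.0, 1.0),
    pit_id: object = None,
) -> PitMeasurement:
    """Measure D, I, P on a pit surface mesh relative to the membrane plane.

    The surface must reach the membrane plane (the pore opening); a surface
    floating above it has no identifiable pore and raises.
    """
    origin, u, v, n = _membrane_frame(membrane_origin, membrane_normal)
    rel = mesh.vertices - origin
    heights = rel @ n
    lateral = np.column_stack([rel @ u, rel @ v])
    edge = float(np.median(
        np.linalg.norm(
            mesh.vertices[mesh.faces[:, 0]] - mesh.vertices[mesh.faces[:, 1]], axis=1
        )
    ))
    return _measure(lateral, heights, edge, pit_id, "3D")


def measure_pit_2d(
    contour: np.ndarray, pit_id: object = None, edge_estimate: float | None = None
) -> PitMeasurement:
    """Same measurement on a 2D section contour ((N, 2) points in (u, z))."""
    contour = np.asarray(contour, dtype=float)
    heights = contour[:, 1]
    lateral = contour[:, :1]
    if edge_estimate is None:
        seg = np.linalg.norm(np.diff(contour, axis=0), axis=1)
        edge_estimate = float(np.median(seg[seg > 0])) * 4.0
    return _measure(lateral, heights, edge_estimate, pit_id, "2D")


# ---------------------------------------------------------------------------
# classification and derived quantities
# ---------------------------------------------------------------------------


def classify_pit(D_nm: float, P_nm: float, eps: float = EQ1_TOLERANCE):
    """Map the D/P ratio to its shape class; flag near-budding events.

    Classes: EQ1 (ratio within ``eps`` of 1), GT1_1p5 (1 < r <= 1.5),
    R1p5_2 (1.5 < r <= 2), GT2 (r > 2).  Near-budding: r > 1.5 with a pore
    narrower than 100 nm.
    """
    if D_nm <= 0 or P_nm <= 0:
        raise ValueError("D and P must be > 0")
    r = D_nm / P_nm
    if r < 1.0 - eps:
        raise ValueError("inconsistent measurement: P exceeds D beyond tolerance")
    if r <= 1.0 + eps:
        cls = "EQ1"
    elif r <= 1.5:
        cls = "GT1_1p5"
    elif r <= 2.0:
        cls = "R1p5_2"
    else:
        cls = "GT2"
    near_budding = bool(r > BUDDING_RATIO and P_nm < BUDDING_PORE_MAX_NM)
    return cls, near_budding


def pit_surface_area(mesh: TriangleMesh, min_valid_fraction: float = 0.4) -> float:
    """Missing-wedge-completed surface area.

    Valid-face area plus the occluded faces reconstructed by radial
    projection onto a least-squares sphere fitted to the valid vertices.
    With no occlusion this is exactly the mesh area.  If the sphere fit is
    degenerate, falls back to the valid-face area with a warning.
    """
    valid = mesh.valid_mask()
    if valid.all():
        return mesh_area(mesh)
    frac = valid.mean()
    if frac < min_valid_fraction:
        raise ValueError(
            f"only {frac:.0%} of faces valid; need >= {min_valid_fraction:.0%}"
        )
    areas = mesh.face_areas
    a_valid = float(areas[valid].sum())
    vert_idx = np.unique(mesh.faces[valid])
    try:
        fit = fit_sphere(mesh.vertices[vert_idx])
    except ValueError:
        warnings.warn("sphere fit degenerate; area incomplete (valid faces only)")
        return a_valid
    c, r = fit.sphere.center, fit.sphere.radius
    tri = mesh.triangles[~valid]
    rel = tri - c
    norms = np.linalg.norm(rel, axis=2, keepdims=True)
    proj = c + r * rel / np.maximum(norms, 1e-12)
    completed = 0.5 * np.linalg.norm(
        np.cross(proj[:, 1] - proj[:, 0], proj[:, 2] - proj[:, 0]), axis=1
    ).sum()
    return a_valid + float(completed)


def sv_equivalents(
    area_nm2: float, d_sv_nm: float = MEAN_DOCKED_SV_DIAMETER_NM
):
    """Invagination area expressed in docked-SV surface areas.

    Returns (raw, rounded); rounded is the nearest integer with a floor of
    1 once the raw value reaches 0.5.
    """
    if area_nm2 <= 0 or d_sv_nm <= 0:
        raise ValueError("area and reference diameter must be > 0")
    raw = area_nm2 / (math.pi * d_sv_nm**2)
    rounded = int(math.floor(raw + 0.5)) if raw >= 0.5 else 0
    rounded = max(rounded, 1) if raw >= 0.5 else rounded
    return raw, rounded


def zone_pit(
    pore_center, az_meshes: list[TriangleMesh], peri_max_nm: float = PERI_AZ_MAX_NM
):
    """peri_AZ if the pore center lies within 200 nm of the nearest AZ edge
    (closed boundary), else distal.  Returns (zone, distance)."""
    if not az_meshes:
        raise ValueError("no AZ mesh")
    p = np.asarray(pore_center, dtype=float)
    if p.shape == (2,):
        p = np.array([p[0], p[1], 0.0])
    d = min(
        point_to_segments_distance(p, m.boundary_segments()) for m in az_meshes
    )
    zone = "peri_AZ" if d <= peri_max_nm else "distal"
    return zone, float(d)


# ---------------------------------------------------------------------------
# census and volume filters
# ---------------------------------------------------------------------------


def _in_bounds(points: np.ndarray, bounds) -> bool:
    lo, hi = np.asarray(bounds[0], float), np.asarray(bounds[1], float)
    return bool(np.all(points >= lo) and np.all(points <= hi))


def filter_census(
    pits: pd.DataFrame,
    pit_meshes: dict | None = None,
    volume_bounds=None,
) -> PitCensus:
    """Apply the in-volume exclusion rules and tabulate incidence.

    ``pits`` needs columns bouton_id, pit_id, coated; optional boolean
    columns midline_in_volume / fully_in_volume override the geometric
    check.  All visible pits count toward incidence; only midline-in-volume
    pits enter the D/I/P table and only fully-contained pits the
    surface-area table.
    """
    pits = pits.copy()
    for col in ("midline_in_volume", "fully_in_volume"):
        if col not in pits.columns:
            if pit_meshes is not None and volume_bounds is not None:
                pits[col] = [
                    _in_bounds(pit_meshes[i].vertices, volume_bounds)
                    for i in pits["pit_id"]
                ]
            else:
                pits[col] = True
    groups = pits.groupby("bouton_id")
    per_bouton = groups.agg(
        n_coated=("coated", "sum"),
        n_noncoated=("coated", lambda s: int((~s.astype(bool)).sum())),
    ).reset_index()
    n_boutons = len(per_bouton)
    return PitCensus(
        per_bouton=per_bouton,
        incidence_coated=per_bouton["n_coated"].sum() / n_boutons if n_boutons else math.nan,
        incidence_noncoated=per_bouton["n_noncoated"].sum() / n_boutons if n_boutons else math.nan,
        n_boutons=n_boutons,
        morphometry_ids=list(pits.loc[pits["midline_in_volume"], "pit_id"]),
        area_ids=list(pits.loc[pits["fully_in_volume"], "pit_id"]),
    )
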