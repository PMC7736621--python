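"""Ground-truthed synthetic inputs for every downstream analysis stage.

The generator emulates the structures a flash-and-freeze EM study of
hippocampal mossy fiber boutons (hMFBs) measures:

* active-zone (AZ) membrane patches — planar disks or spherical caps of
  controllable area and curvature, at z = 0 with the cytoplasm at z > 0;
* vesicle populations around the 60-nm SV/GV diameter boundary, with
  controllable docked fractions (membrane gap drawn in [0, 2] nm) and
  radial distance distributions over 0-100 nm;
* omega-shaped endocytic pits modelled as a sphere (radius R) joined to
  the membrane by a cylindrical neck (pore radius p <= R, length L), which
  reproduces the D/P shape regimes with three interpretable parameters:
  true D = 2R, P = 2p, I = L + R + sqrt(R^2 - p^2);
* missing-wedge occlusion from a limited tilt range (default +/-60 deg);
* 60-nm slab sectioning into 2D profiles with their stereological
  underestimation of diameters;
* two-channel nuclei images (DAPI-like disks + per-nucleus marker
  intensity) for the Cre-positivity pipeline.

Every output is a pure function of (spec, seed): the seed lives on the
spec and is recorded in every artifact.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import Delaunay

from .geometry import (
    PolyLine2D,
    SphereModel,
    TriangleMesh,
    point_to_disk_distance,
)

__all__ = [
    "SceneSpec",
    "WedgeSpec",
    "NucleiImageSpec",
    "PitModel",
    "SynapseScene",
    "AZProfile2D",
    "PitProfile2D",
    "SectionProfile2D",
    "generate_scene",
    "apply_missing_wedge",
    "occlude_mesh",
    "section_scene",
    "generate_nuclei_image",
    "save_nuclei_image",
    "load_nuclei_image",
    "disk_mesh",
    "spherical_cap_mesh",
    "pit_mesh",
]


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class SceneSpec:
    """Parameters of one synthetic bouton ("tomogram").

    Defaults describe a well-powered resting (NS) hMFB active zone:
    ~0.05 um^2 AZ area, 30 vesicles segmented within 100 nm of the AZ,
    30% of them docked, diameters centered on 46 nm (SV) and 75 nm (GV).
    """

    seed: int = 0
    condition: str = "NS"
    bouton_id: str = "bouton-0"
    az_count: int = 1
    az_area_mean_nm2: float = 80_000.0
    az_area_sd_nm2: float = 8_000.0
    az_curvature_radius_nm: float = math.inf  # inf = planar patch
    n_sv: int = 30
    n_gv: int = 3
    n_dcv: int = 1
    sv_diameter_mean_nm: float = 46.0
    sv_diameter_sd_nm: float = 5.0
    gv_diameter_mean_nm: float = 75.0
    gv_diameter_sd_nm: float = 8.0
    dcv_diameter_mean_nm: float = 80.0
    dcv_diameter_sd_nm: float = 10.0
    docked_fraction: float = 0.30
    docked_gv_fraction: float = 0.15
    docked_gap_range_nm: tuple[float, float] = (0.0, 2.0)
    undocked_distance_range_nm: tuple[float, float] = (2.0, 100.0)
    pit_rate: float = 0.0  # mean pit count per bouton (Poisson)
    pit_radius_mean_nm: float = 44.7
    pit_radius_sd_nm: float = 8.0
    pit_radius_bounds_nm: tuple[float, float] = (25.0, 80.0)
    pit_pore_ratio_range: tuple[float, float] = (0.35, 1.0)  # p / R
    pit_neck_range_nm: tuple[float, float] = (0.0, 30.0)
    pit_coated_prob: float = 0.1
    pit_az_distance_range_nm: tuple[float, float] = (20.0, 400.0)
    mesh_edge_nm: float = 2.0
    az_mesh_edge_nm: float = 6.0
    membrane_radius_nm: float = 700.0
    membrane_mesh_edge_nm: float = 40.0
    max_placement_retries: int = 500

    def validate(self) -> None:
        if min(self.az_count, self.n_sv, self.n_gv, self.n_dcv) < 0:
            raise ValueError("counts must be >= 0")
        if self.pit_rate < 0:
            raise ValueError("pit_rate must be >= 0")
        lo, hi = self.pit_pore_ratio_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("pore ratio must satisfy 0 < p/R <= 1")
        if not (0 <= self.docked_fraction <= 1 and 0 <= self.docked_gv_fraction <= 1):
            raise ValueError("docked fractions must be in [0, 1]")


@dataclasses.dataclass
class WedgeSpec:
    """Missing-wedge occlusion implied by a limited tilt range.

    A tilt series spanning +/-``tilt_range_deg`` leaves a blind cone of
    half-angle (90 - tilt_range) around the beam axis: surfaces whose
    normals fall inside that cone are poorly resolved.
    """

    tilt_range_deg: float = 60.0
    beam_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        if not (0.0 < self.tilt_range_deg <= 90.0):
            raise ValueError("tilt range must be in (0, 90]")

    @property
    def occlusion_half_angle_deg(self) -> float:
        return 90.0 - self.tilt_range_deg


@dataclasses.dataclass
class NucleiImageSpec:
    """Synthetic two-channel (nuclear stain + marker) confocal field."""

    seed: int = 0
    shape: tuple[int, int] = (512, 512)
    pixel_size_um: float = 0.189
    n_target: int = 80
    n_background: int = 20
    radius_mean_px: float = 12.0
    radius_sd_px: float = 1.5
    blur_sigma_px: float = 2.0
    noise_sd: float = 4.0
    positive_fraction: float = 0.912
    background_region_frac: float = 0.25  # left strip = background region
    dapi_intensity: float = 180.0
    background_intensity: float = 10.0
    positive_mean: float = 120.0
    negative_mean: float = 40.0
    intensity_sd: float = 10.0
    min_separation_factor: float = 2.4
    bit_max: float = 255.0

    def validate(self) -> None:
        if not (0.0 <= self.positive_fraction <= 1.0):
            raise ValueError("positive fraction must be in [0, 1]")
        for v in (self.dapi_intensity, self.positive_mean, self.negative_mean):
            if not (0 <= v <= self.bit_max):
                raise ValueError("intensities must lie within the bit depth")


# ---------------------------------------------------------------------------
# scene containers
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class PitModel:
    """Parametric omega pit: sphere (radius R) on a cylindrical neck.

    The pore (radius ``p``) lies on the membrane plane at ``pore_center``;
    the neck rises to z = L where it joins the sphere, whose center sits at
    z = L + sqrt(R^2 - p^2).
    """

    radius_nm: float  # R
    pore_radius_nm: float  # p <= R
    neck_length_nm: float  # L >= 0
    pore_center: tuple[float, float] = (0.0, 0.0)
    coated: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.pore_radius_nm <= self.radius_nm):
            raise ValueError("pore radius must satisfy 0 < p <= R")
        if self.neck_length_nm < 0:
            raise ValueError("neck length must be >= 0")

    @property
    def sphere_center_z(self) -> float:
        R, p = self.radius_nm, self.pore_radius_nm
        return self.neck_length_nm + math.sqrt(R * R - p * p)

    @property
    def true_D(self) -> float:
        return 2.0 * self.radius_nm

    @property
    def true_P(self) -> float:
        return 2.0 * self.pore_radius_nm

    @property
    def true_I(self) -> float:
        R, p = self.radius_nm, self.pore_radius_nm
        return self.neck_length_nm + R + math.sqrt(R * R - p * p)

    @property
    def true_area(self) -> float:
        """Analytic membrane area: spherical zone + cylindrical neck wall."""
        R, p = self.radius_nm, self.pore_radius_nm
        zone = 2.0 * math.pi * R * (R + math.sqrt(R * R - p * p))
        return zone + 2.0 * math.pi * p * self.neck_length_nm

    def mesh(self, edge_nm: float = 2.0) -> TriangleMesh:
        return pit_mesh(self, edge_nm)


@dataclasses.dataclass
class SynapseScene:
    """One synthetic bouton with its full ground-truth bookkeeping."""

    bouton_id: str
    condition: str
    seed: int
    az_meshes: list[TriangleMesh]
    az_params: pd.DataFrame  # az_id, cx, cy, footprint_radius_nm, area_nm2, curvature_radius_nm
    membrane: TriangleMesh
    vesicles: pd.DataFrame  # vesicle_id, x, y, z, diameter_nm, dense_core,
    #                         true_class, true_distance_nm, true_docked, az_id
    pits: list[PitModel]
    pit_meshes: list[TriangleMesh]
    pit_truth: pd.DataFrame  # pit_id, true_D/P/I/area, az_edge_distance_nm, zone, coated
    spec: SceneSpec | None = None

    @property
    def az_areas(self) -> np.ndarray:
        return self.az_params["area_nm2"].to_numpy()


# ---------------------------------------------------------------------------
# mesh builders
# ---------------------------------------------------------------------------


def disk_mesh(radius: float, edge: float, center=(0.0, 0.0, 0.0)) -> TriangleMesh:
    """Planar disk at z = const, triangulated from concentric rings."""
    n_r = max(1, int(math.ceil(radius / edge)))
    pts = [(0.0, 0.0)]
    for i in range(1, n_r + 1):
        r = radius * i / n_r
        m = max(8, int(math.ceil(2.0 * math.pi * r / edge)))
        ang = 2.0 * math.pi * np.arange(m) / m
        pts.extend(zip(r * np.cos(ang), r * np.sin(ang)))
    pts2 = np.asarray(pts)
    faces = Delaunay(pts2).simplices
    v3 = np.column_stack([pts2, np.zeros(len(pts2))]) + np.asarray(center)
    # orient all faces with +z normal
    tri = pts2[faces]
    e1 = tri[:, 1] - tri[:, 0]
    e2 = tri[:, 2] - tri[:, 0]
    flip = e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0] < 0
    faces[flip] = faces[flip][:, ::-1]
    return TriangleMesh(v3, faces)


def _lat_long_surface(rings: Sequence[np.ndarray], apex: np.ndarray | None = None) -> TriangleMesh:
    """Stitch rings of equal azimuthal count into quad strips (+ apex fan)."""
    m = len(rings[0])
    verts = [np.asarray(r) for r in rings]
    vertices = np.concatenate(verts, axis=0)
    faces = []
    for k in range(len(rings) - 1):
        base0 = k * m
        base1 = (k + 1) * m
        for j in range(m):
            jn = (j + 1) % m
            faces.append([base0 + j, base0 + jn, base1 + j])
            faces.append([base0 + jn, base1 + jn, base1 + j])
    if apex is not None:
        apex_idx = len(vertices)
        vertices = np.vstack([vertices, apex])
        base = (len(rings) - 1) * m
        for j in range(m):
            jn = (j + 1) % m
            faces.append([base + j, base + jn, apex_idx])
    return TriangleMesh(vertices, np.asarray(faces, dtype=np.int64))


def spherical_cap_mesh(
    sphere_radius: float,
    polar_angle_max: float,
    edge: float,
    center=(0.0, 0.0, 0.0),
    pole_direction=(0.0, 0.0, 1.0),
) -> TriangleMesh:
    """Cap of a sphere around ``pole_direction`` out to ``polar_angle_max``."""
    R = float(sphere_radius)
    m = max(12, int(math.ceil(2.0 * math.pi * R / edge)))
    n_theta = max(2, int(math.ceil(polar_angle_max * R / edge)))
    thetas = polar_angle_max * np.arange(n_theta, 0, -1) / n_theta
    ang = 2.0 * math.pi * np.arange(m) / m
    rings = []
    for th in thetas:
        r = R * math.sin(th)
        z = R * math.cos(th)
        rings.append(np.column_stack([r * np.cos(ang), r * np.sin(ang), np.full(m, z)]))
    mesh = _lat_long_surface(rings, apex=np.array([0.0, 0.0, R]))
    u = np.asarray(pole_direction, dtype=float)
    u /= np.linalg.norm(u)
    rot = _rotation_from_z(u)
    v = mesh.vertices @ rot.T + np.asarray(center)
    return TriangleMesh(v, mesh.faces)


def _rotation_from_z(u: np.ndarray) -> np.ndarray:
    """Rotation matrix sending +z to unit vector u."""
    z = np.array([0.0, 0.0, 1.0])
    c = float(np.dot(z, u))
    if c > 1 - 1e-12:
        return np.eye(3)
    if c < -1 + 1e-12:
        return np.diag([1.0, -1.0, -1.0])
    axis = np.cross(z, u)
    s = np.linalg.norm(axis)
    axis = axis / s
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + s * K + (1 - c) * (K @ K)


def pit_mesh(pit: PitModel, edge_nm: float = 2.0) -> TriangleMesh:
    """Triangulate the sphere + neck surface down to the membrane plane."""
    R, p, L = pit.radius_nm, pit.pore_radius_nm, pit.neck_length_nm
    zc = pit.sphere_center_z
    m = max(16, int(math.ceil(2.0 * math.pi * R / edge_nm)))
    ang = 2.0 * math.pi * np.arange(m) / m
    cos_a, sin_a = np.cos(ang), np.sin(ang)

    rings: list[np.ndarray] = []
    # neck wall: z from 0 up to the sphere junction
    z_j = zc - math.sqrt(R * R - p * p)
    if L > 0:
        n_z = max(1, int(math.ceil(L / edge_nm)))
        for z in np.linspace(0.0, L, n_z + 1):
            rings.append(np.column_stack([p * cos_a, p * sin_a, np.full(m, z)]))
    else:
        rings.append(np.column_stack([p * cos_a, p * sin_a, np.zeros(m)]))
    # spherical zone: polar angle from junction up to (near) the tip
    theta_j = math.pi - math.asin(min(1.0, p / R))  # measured from +z (tip)
    n_theta = max(2, int(math.ceil(theta_j * R / edge_nm)))
    thetas = theta_j * np.arange(n_theta, 0, -1) / n_theta
    for th in thetas:
        r = R * math.sin(th)
        z = zc + R * math.cos(th)
        rings.append(np.column_stack([r * cos_a, r * sin_a, np.full(m, z)]))
    mesh = _lat_long_surface(rings, apex=np.array([0.0, 0.0, zc + R]))
    cx, cy = pit.pore_center
    v = mesh.vertices + np.array([cx, cy, 0.0])
    return TriangleMesh(v, mesh.faces)


# ---------------------------------------------------------------------------
# analytic AZ distance (truth table)
# ---------------------------------------------------------------------------


def _point_to_az_distance(
    p: np.ndarray, cx: float, cy: float, footprint_radius: float, curvature_radius: float
) -> float:
    if math.isinf(curvature_radius):
        return point_to_disk_distance(
            p, np.array([cx, cy, 0.0]), np.array([0.0, 0.0, 1.0]), footprint_radius
        )
    # spherical cap, apex at (cx, cy, 0), sphere center at z = +Rc
    Rc = curvature_radius
    center = np.array([cx, cy, Rc])
    d = np.asarray(p, dtype=float) - center
    norm = np.linalg.norm(d)
    theta = math.acos(np.clip(-d[2] / norm, -1.0, 1.0))  # angle from apex axis (-z)
    h = _cap_height(footprint_radius, Rc)
    theta_max = math.acos(1.0 - h / Rc)
    if theta <= theta_max:
        return abs(norm - Rc)
    # distance to the rim circle
    rim_r = Rc * math.sin(theta_max)
    rim_z = Rc * (1.0 - math.cos(theta_max))
    rho = math.hypot(p[0] - cx, p[1] - cy)
    return math.hypot(rho - rim_r, p[2] - rim_z)


def _cap_height(area_equiv_radius: float, Rc: float) -> float:
    """Cap height giving the same area as a planar disk of that radius."""
    area = math.pi * area_equiv_radius**2
    return area / (2.0 * math.pi * Rc)


# ---------------------------------------------------------------------------
# scene generation
# ---------------------------------------------------------------------------


def _truncnorm(rng: np.random.Generator, mean, sd, lo, hi, size) -> np.ndarray:
    out = np.empty(size)
    for i in range(size):
        for _ in range(1000):
            x = rng.normal(mean, sd)
            if lo <= x <= hi:
                out[i] = x
                break
        else:
            out[i] = float(np.clip(mean, lo, hi))
    return out


def generate_scene(spec: SceneSpec) -> SynapseScene:
    """Build one ground-truthed synthetic bouton from its spec (pure in seed)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    # --- active zones -----------------------------------------------------
    az_rows = []
    az_meshes = []
    offset = 0.0
    for a in range(spec.az_count):
        area = max(5_000.0, rng.normal(spec.az_area_mean_nm2, spec.az_area_sd_nm2))
        foot_r = math.sqrt(area / math.pi)
        cx, cy = offset, 0.0
        if math.isinf(spec.az_curvature_radius_nm):
            mesh = disk_mesh(foot_r, spec.az_mesh_edge_nm, center=(cx, cy, 0.0))
        else:
            Rc = spec.az_curvature_radius_nm
            h = _cap_height(foot_r, Rc)
            theta_max = math.acos(max(-1.0, 1.0 - h / Rc))
            cap = spherical_cap_mesh(
                Rc, theta_max, spec.az_mesh_edge_nm, center=(cx, cy, Rc),
                pole_direction=(0.0, 0.0, -1.0),
            )
            mesh = cap
        az_meshes.append(mesh)
        az_rows.append(
            dict(az_id=a, cx=cx, cy=cy, footprint_radius_nm=foot_r,
                 area_nm2=area, curvature_radius_nm=spec.az_curvature_radius_nm)
        )
        offset += 4.0 * foot_r  # keep multiple AZs well separated
    az_params = pd.DataFrame(az_rows)

    # --- vesicles ---------------------------------------------------------
    classes = (
        ["SV"] * spec.n_sv + ["GV"] * spec.n_gv + ["DCV"] * spec.n_dcv
    )
    diam = np.concatenate([
        _truncnorm(rng, spec.sv_diameter_mean_nm, spec.sv_diameter_sd_nm, 25.0, 59.5, spec.n_sv),
        _truncnorm(rng, spec.gv_diameter_mean_nm, spec.gv_diameter_sd_nm, 60.5, 120.0, spec.n_gv),
        _truncnorm(rng, spec.dcv_diameter_mean_nm, spec.dcv_diameter_sd_nm, 50.0, 130.0, spec.n_dcv),
    ]) if classes else np.empty(0)
    n_total = len(classes)
    docked = np.zeros(n_total, dtype=bool)
    docked[: round(spec.docked_fraction * spec.n_sv)] = True  # SVs first
    gv0 = spec.n_sv
    docked[gv0 : gv0 + round(spec.docked_gv_fraction * spec.n_gv)] = True

    rows = []
    placed: list[tuple[np.ndarray, float]] = []
    # place large vesicles first: rejection sampling packs them more easily
    order = sorted(range(n_total), key=lambda i: -diam[i])
    for i in order:
        r = diam[i] / 2.0
        az_id = int(rng.integers(spec.az_count)) if spec.az_count else 0
        arow = az_rows[az_id]
        gap_range = (
            spec.docked_gap_range_nm if docked[i] else spec.undocked_distance_range_nm
        )
        ok = False
        for _ in range(spec.max_placement_retries):
            gap = rng.uniform(*gap_range)
            # place above the AZ footprint so the analytic distance is exact
            rho = arow["footprint_radius_nm"] * math.sqrt(rng.uniform(0.0, 0.9))
            phi = rng.uniform(0.0, 2.0 * math.pi)
            cx = arow["cx"] + rho * math.cos(phi)
            cy = arow["cy"] + rho * math.sin(phi)
            if math.isinf(spec.az_curvature_radius_nm):
                z = gap + r
                center = np.array([cx, cy, z])
            else:
                # along the local inward normal of the cap
                Rc = spec.az_curvature_radius_nm
                sc = np.array([arow["cx"], arow["cy"], Rc])
                surf_dir = np.array([cx - arow["cx"], cy - arow["cy"], -Rc])
                surf_dir /= np.linalg.norm(surf_dir)
                surf_pt = sc + Rc * surf_dir
                center = surf_pt - surf_dir * (gap + r)  # inward (toward cytoplasm)
            if all(
                np.linalg.norm(center - c0) > (r + r0)
                for c0, r0 in placed
            ):
                ok = True
                break
        if not ok:
            raise RuntimeError(
                f"infeasible vesicle placement (seed={spec.seed}, vesicle {i})"
            )
        placed.append((center, r))
        true_dist = min(
            _point_to_az_distance(
                center, a["cx"], a["cy"], a["footprint_radius_nm"],
                a["curvature_radius_nm"],
            ) - r
            for a in az_rows
        )
        true_dist = max(true_dist, 0.0)
        rows.append(
            dict(
                vesicle_id=i, x=center[0], y=center[1], z=center[2],
                diameter_nm=diam[i], dense_core=(classes[i] == "DCV"),
                true_class=classes[i], true_distance_nm=true_dist,
                true_docked=bool(true_dist <= spec.docked_gap_range_nm[1]) and docked[i],
                az_id=az_id,
            )
        )
    vesicles = pd.DataFrame(
        rows,
        columns=[
            "vesicle_id", "x", "y", "z", "diameter_nm", "dense_core",
            "true_class", "true_distance_nm", "true_docked", "az_id",
        ],
    ).sort_values("vesicle_id", ignore_index=True)

    # --- pits -------------------------------------------------------------
    n_pits = int(rng.poisson(spec.pit_rate)) if spec.pit_rate > 0 else 0
    pits: list[PitModel] = []
    pit_meshes: list[TriangleMesh] = []
    truth_rows = []
    max_foot = az_params["footprint_radius_nm"].max() if len(az_params) else 0.0
    for k in range(n_pits):
        R = float(
            _truncnorm(
                rng, spec.pit_radius_mean_nm, spec.pit_radius_sd_nm,
                *spec.pit_radius_bounds_nm, 1,
            )[0]
        )
        ratio = rng.uniform(*spec.pit_pore_ratio_range)
        p = ratio * R
        L = rng.uniform(*spec.pit_neck_range_nm)
        d_edge = rng.uniform(*spec.pit_az_distance_range_nm)
        phi = rng.uniform(0.0, 2.0 * math.pi)
        arow = az_rows[int(rng.integers(spec.az_count))] if spec.az_count else dict(cx=0, cy=0, footprint_radius_nm=0)
        rad = arow["footprint_radius_nm"] + d_edge + p
        cx = arow["cx"] + rad * math.cos(phi)
        cy = arow["cy"] + rad * math.sin(phi)
        pit = PitModel(R, p, L, pore_center=(cx, cy), coated=bool(rng.random() < spec.pit_coated_prob))
        pits.append(pit)
        pit_meshes.append(pit.mesh(spec.mesh_edge_nm))
        # distance from the pore center to the nearest AZ edge (rim circle)
        d_az = min(
            max(math.hypot(cx - a["cx"], cy - a["cy"]) - a["footprint_radius_nm"], 0.0)
            for a in az_rows
        ) if az_rows else math.nan
        truth_rows.append(
            dict(
                pit_id=k, radius_nm=R, pore_radius_nm=p, neck_length_nm=L,
                true_D=pit.true_D, true_P=pit.true_P, true_I=pit.true_I,
                true_area_nm2=pit.true_area, az_edge_distance_nm=d_az,
                zone="peri_AZ" if d_az <= 200.0 else "distal",
                coated=pit.coated,
            )
        )
    pit_truth = pd.DataFrame(
        truth_rows,
        columns=[
            "pit_id", "radius_nm", "pore_radius_nm", "neck_length_nm",
            "true_D", "true_P", "true_I", "true_area_nm2",
            "az_edge_distance_nm", "zone", "coated",
        ],
    )

    membrane = disk_mesh(spec.membrane_radius_nm, spec.membrane_mesh_edge_nm)
    return SynapseScene(
        bouton_id=spec.bouton_id, condition=spec.condition, seed=spec.seed,
        az_meshes=az_meshes, az_params=az_params, membrane=membrane,
        vesicles=vesicles, pits=pits, pit_meshes=pit_meshes,
        pit_truth=pit_truth, spec=spec,
    )


# ---------------------------------------------------------------------------
# missing wedge
# ---------------------------------------------------------------------------


def occlude_mesh(mesh: TriangleMesh, wedge: WedgeSpec) -> TriangleMesh:
    """Flag faces whose normals fall inside the blind cone as invalid."""
    beam = np.asarray(wedge.beam_axis, dtype=float)
    beam /= np.linalg.norm(beam)
    cos_thresh = math.cos(math.radians(wedge.occlusion_half_angle_deg))
    if wedge.occlusion_half_angle_deg <= 0.0:
        valid = np.ones(len(mesh.faces), dtype=bool)
    else:
        cosang = np.abs(mesh.face_normals @ beam)
        valid = cosang < cos_thresh
    return TriangleMesh(mesh.vertices.copy(), mesh.faces.copy(), valid)


def apply_missing_wedge(scene: SynapseScene, wedge: WedgeSpec) -> SynapseScene:
    """Occlude every surface of a scene; ground truth is untouched."""
    return dataclasses.replace(
        scene,
        az_meshes=[occlude_mesh(m, wedge) for m in scene.az_meshes],
        pit_meshes=[occlude_mesh(m, wedge) for m in scene.pit_meshes],
        membrane=occlude_mesh(scene.membrane, wedge),
    )


# ---------------------------------------------------------------------------
# sectioning
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class AZProfile2D:
    az_id: int
    polyline: PolyLine2D  # (u, z) in the section plane, nm
    segment_tilt_deg: np.ndarray  # AZ surface tilt vs the section plane, per segment


@dataclasses.dataclass
class PitProfile2D:
    pit_id: int
    contour: np.ndarray  # (N, 2) in (u, z)
    apparent_D: float
    apparent_P: float
    apparent_I: float


@dataclasses.dataclass
class SectionProfile2D:
    """One slab's worth of 2D profiles (the ultrathin-section emulation)."""

    bouton_id: str
    condition: str
    thickness_nm: float
    offset_nm: float
    az_profiles: list[AZProfile2D]
    vesicles: pd.DataFrame  # vesicle_id, u, z, apparent_diameter_nm, true_diameter_nm
    pit_profiles: list[PitProfile2D]


def _chain_segments(segs: np.ndarray, tilts: np.ndarray, tol: float = 1e-6):
    """Greedy-chain 2D segments that share endpoints into ordered polylines."""
    remaining = list(range(len(segs)))
    chains = []
    while remaining:
        i = remaining.pop(0)
        pts = [segs[i, 0], segs[i, 1]]
        ts = [tilts[i]]
        grew = True
        while grew:
            grew = False
            for j in list(remaining):
                a, b = segs[j]
                if np.linalg.norm(a - pts[-1]) < tol:
                    pts.append(b)
                    ts.append(tilts[j])
                elif np.linalg.norm(b - pts[-1]) < tol:
                    pts.append(a)
                    ts.append(tilts[j])
                elif np.linalg.norm(b - pts[0]) < tol:
                    pts.insert(0, a)
                    ts.insert(0, tilts[j])
                elif np.linalg.norm(a - pts[0]) < tol:
                    pts.insert(0, b)
                    ts.insert(0, tilts[j])
                else:
                    continue
                remaining.remove(j)
                grew = True
        chains.append((np.asarray(pts), np.asarray(ts)))
    return chains


def _mesh_plane_profiles(mesh: TriangleMesh, x_mid: float) -> list[tuple[np.ndarray, np.ndarray]]:
    """Intersect a mesh with the plane x = x_mid -> [(points(u,z), seg tilts)]."""
    import trimesh.intersections as ti

    tm = mesh.to_trimesh()
    result = ti.mesh_plane(
        tm, plane_normal=[1.0, 0.0, 0.0], plane_origin=[x_mid, 0.0, 0.0],
        return_faces=True,
    )
    segs3, face_idx = result
    if len(segs3) == 0:
        return []
    normals = mesh.face_normals[face_idx]
    # tilt of the AZ surface relative to the section plane: 0 when the
    # surface is perpendicular to the section (normal in-plane)
    cos_to_axis = np.abs(normals[:, 0])
    tilt = np.degrees(np.arcsin(np.clip(cos_to_axis, 0.0, 1.0)))
    segs2 = segs3[:, :, 1:]  # (u, z) = (y, z)
    # deduplicate consecutive identical points later in chaining
    return _chain_segments(segs2, tilt, tol=1e-9)


def section_scene(
    scene: SynapseScene, thickness_nm: float = 60.0, offset_nm: float = 0.0
) -> SectionProfile2D:
    """Cut a slab offset..offset+thickness along x and project into 2D.

    Sections run perpendicular to the membrane plane (as ultrathin sections
    cut across a bouton do), so AZ patches appear as polylines and spheres
    as circles whose apparent diameter is the largest chord inside the slab.
    """
    if thickness_nm <= 0:
        raise ValueError("thickness must be > 0")
    x0, x1 = offset_nm, offset_nm + thickness_nm
    x_mid = 0.5 * (x0 + x1)

    az_profiles = []
    for az_id, mesh in enumerate(scene.az_meshes):
        for pts, tilts in _mesh_plane_profiles(mesh, x_mid):
            keep = np.ones(len(pts), dtype=bool)
            keep[1:] = np.linalg.norm(np.diff(pts, axis=0), axis=1) > 1e-12
            pts = pts[keep]
            if len(pts) < 2:
                continue
            az_profiles.append(AZProfile2D(az_id, PolyLine2D(pts), tilts))

    rows = []
    for v in scene.vesicles.itertuples():
        r = v.diameter_nm / 2.0
        if x0 <= v.x <= x1:
            app = v.diameter_nm
        else:
            u = min(abs(v.x - x0), abs(v.x - x1))
            app = 2.0 * math.sqrt(r * r - u * u) if u < r else 0.0
        if app <= 0.0:
            continue
        rows.append(
            dict(vesicle_id=v.vesicle_id, u=v.y, z=v.z,
                 apparent_diameter_nm=app, true_diameter_nm=v.diameter_nm)
        )
    vesicles = pd.DataFrame(
        rows, columns=["vesicle_id", "u", "z", "apparent_diameter_nm", "true_diameter_nm"]
    )

    pit_profiles = []
    for k, pit in enumerate(scene.pits):
        cx, cy = pit.pore_center
        c = abs(x_mid - cx)
        if c >= pit.pore_radius_nm:
            continue  # neck not cut: no connected omega profile in this section
        R, p, L = pit.radius_nm, pit.pore_radius_nm, pit.neck_length_nm
        zc = pit.sphere_center_z
        rho = math.sqrt(R * R - c * c)
        w_n = math.sqrt(p * p - c * c)
        z_j = zc - math.sqrt(R * R - p * p)
        # contour: up one neck wall, over the bulb arc (through the tip),
        # down the other wall.  Left junction angle mapped into (pi/2, 3pi/2]
        # and right junction into [-pi/2, 0] so the decreasing sweep always
        # crosses +pi/2 (the tip).
        a0 = math.atan2(z_j - zc, -w_n)
        if a0 <= 0.0:
            a0 += 2.0 * math.pi
        a1 = math.atan2(z_j - zc, w_n)
        angs = np.linspace(a0, a1, 200)
        arc = np.column_stack([cy + rho * np.cos(angs), zc + rho * np.sin(angs)])
        left = np.column_stack([np.full(6, cy - w_n), np.linspace(0.0, z_j, 6)])
        right = np.column_stack([np.full(6, cy + w_n), np.linspace(z_j, 0.0, 6)])
        contour = np.vstack([left, arc, right])
        pit_profiles.append(
            PitProfile2D(
                pit_id=k, contour=contour,
                apparent_D=2.0 * rho, apparent_P=2.0 * w_n,
                apparent_I=zc + rho,
            )
        )

    return SectionProfile2D(
        bouton_id=scene.bouton_id, condition=scene.condition,
        thickness_nm=thickness_nm, offset_nm=offset_nm,
        az_profiles=az_profiles, vesicles=vesicles, pit_profiles=pit_profiles,
    )


# ---------------------------------------------------------------------------
# nuclei images
# ---------------------------------------------------------------------------


def generate_nuclei_image(spec: NucleiImageSpec):
    """Two-channel image + ground-truth nucleus table + target-region mask.

    Channel 0 emulates a nuclear stain (blurred noisy disks); channel 1
    carries a per-nucleus marker intensity drawn from the positive or
    negative distribution.  Nuclei in the left strip of the image are the
    "background" population (all marker-negative), emulating nuclei outside
    the principal cell layer used to set the positivity threshold.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    split = int(round(spec.background_region_frac * w))
    region_mask = np.zeros((h, w), dtype=bool)
    region_mask[:, split:] = True  # True = target region

    min_sep = spec.min_separation_factor * spec.radius_mean_px
    margin = spec.radius_mean_px + 3.0 * spec.radius_sd_px + 2.0

    def place(n, x_lo, x_hi, existing):
        if n > 0 and (h - 2 * margin <= 0 or (x_hi - x_lo) - 2 * margin <= 0):
            raise ValueError("nucleus count infeasible for image size")
        centers = []
        tries = 0
        while len(centers) < n:
            tries += 1
            if tries > 20_000:
                raise ValueError("nucleus count infeasible for image size")
            cy = rng.uniform(margin, h - margin)
            cx = rng.uniform(x_lo + margin, x_hi - margin)
            cand = np.array([cy, cx])
            if all(np.linalg.norm(cand - e) >= min_sep for e in existing + centers):
                centers.append(cand)
        return centers

    bg_centers = place(spec.n_background, 0, split, []) if spec.n_background else []
    tg_centers = place(spec.n_target, split, w, bg_centers) if spec.n_target else []

    n_pos = int(round(spec.positive_fraction * spec.n_target))
    positive = np.zeros(spec.n_target, dtype=bool)
    positive[:n_pos] = True
    rng.shuffle(positive)

    yy, xx = np.mgrid[0:h, 0:w]
    ch1 = np.full((h, w), spec.background_intensity, dtype=float)
    ch2 = np.full((h, w), spec.background_intensity, dtype=float)
    rows = []
    nid = 0
    for region, centers in (("background", bg_centers), ("target", tg_centers)):
        for j, (cy, cx) in enumerate(centers):
            radius = max(4.0, rng.normal(spec.radius_mean_px, spec.radius_sd_px))
            is_pos = region == "target" and bool(positive[j])
            mean = spec.positive_mean if is_pos else spec.negative_mean
            inten = float(np.clip(rng.normal(mean, spec.intensity_sd), 0, spec.bit_max))
            disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
            ch1[disk] = spec.dapi_intensity
            ch2[disk] = inten
            rows.append(
                dict(nucleus_id=nid, cy=cy, cx=cx, radius_px=radius,
                     region=region, true_positive=is_pos, true_intensity=inten)
            )
            nid += 1
    ch1 = ndimage.gaussian_filter(ch1, spec.blur_sigma_px)
    ch2 = ndimage.gaussian_filter(ch2, spec.blur_sigma_px / 2.0)
    ch1 += rng.normal(0.0, spec.noise_sd, size=ch1.shape)
    ch2 += rng.normal(0.0, spec.noise_sd, size=ch2.shape)
    img = np.clip(np.stack([ch1, ch2]), 0.0, spec.bit_max).astype(np.float32)
    truth = pd.DataFrame(
        rows,
        columns=["nucleus_id", "cy", "cx", "radius_px", "region",
                 "true_positive", "true_intensity"],
    )
    return img, truth, region_mask


def save_nuclei_image(image: np.ndarray, path) -> None:
    """Write a (C, H, W) stack as a multi-channel TIFF."""
    import tifffile

    tifffile.imwrite(path, np.asarray(image))


def load_nuclei_image(path) -> np.ndarray:
    import tifffile

    return tifffile.imread(path)
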