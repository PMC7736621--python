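"""Vesicle classification and AZ-relative spatial density readouts.

Implements the study's vesicle bookkeeping: the 60-nm SV/GV diameter
boundary (dense-cored vesicles are their own class regardless of size),
shortest membrane-to-membrane distances to the nearest active zone,
docked scoring (gap <= 2 nm in 3D by default), binned spatial densities
normalized to AZ area (3D) or per 100 nm of AZ length (2D), and
normalization of per-AZ metrics to the unstimulated control condition.

Binning convention: bins are closed on the right with ties at an edge
going to the lower bin, and the first bin includes 0 — i.e. the docked
bin is exactly the [0, 2] nm gap interval.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .geometry import (
    PolyLine2D,
    SphereModel,
    TriangleMesh,
    point_to_polyline_distance,
    points_to_mesh_distance,
)
from .synthetic import SectionProfile2D, SynapseScene

__all__ = [
    "BinScheme",
    "AZDensityProfile",
    "classify_vesicle",
    "assign_distances",
    "density_profile_3d",
    "density_profile_2d",
    "include_az_2d",
    "normalize_to_control",
]

SV_GV_BOUNDARY_NM = 60.0
DOCKED_MAX_GAP_NM = 2.0
GV_WINDOW_NM = 40.0  # docked-GV fraction is taken among GVs within 0-40 nm


@dataclasses.dataclass
class BinScheme:
    """Ordered distance bin edges (nm), starting at 0."""

    edges: tuple[float, ...] = (0.0, 2.0, 5.0, 10.0, 40.0, 60.0, 100.0)
    diameter_bin_width_nm: float = 2.0

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, dtype=float)
        if e[0] != 0.0 or np.any(np.diff(e) <= 0):
            raise ValueError("edges must be strictly increasing from 0")

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    def assign(self, distances: np.ndarray) -> np.ndarray:
        """Bin index per distance; -1 = beyond the outer edge.

        Ties at an edge go to the lower bin; 0 belongs to the first bin.
        """
        d = np.asarray(distances, dtype=float)
        idx = np.searchsorted(self.edges, d, side="left") - 1
        idx[d == 0.0] = 0
        idx[d > self.edges[-1]] = -1
        return idx


@dataclasses.dataclass
class AZDensityProfile:
    """Per-AZ binned counts and densities for one reference AZ."""

    az_id: object
    denominator: float  # AZ area (nm^2, 3D) or AZ length (nm, 2D)
    dimension: str  # "3D" | "2D"
    edges: tuple[float, ...]
    counts_sv: np.ndarray
    counts_gv: np.ndarray
    density_sv: np.ndarray  # 3D: SV / um^2; 2D: vesicles per 100 nm AZ
    density_gv: np.ndarray
    docked_gv_count: int = 0
    gv_within_window: int = 0
    skipped: bool = False
    extra: dict = dataclasses.field(default_factory=dict)

    @property
    def docked_gv_fraction(self) -> float:
        if self.gv_within_window == 0:
            return float("nan")
        return self.docked_gv_count / self.gv_within_window


def classify_vesicle(diameter_nm: float, dense_core: bool) -> str:
    """SV (< 60 nm), GV (>= 60 nm, no core), or DCV (prominent dense core)."""
    if diameter_nm <= 0:
        raise ValueError("diameter must be > 0")
    if dense_core:
        return "DCV"
    return "SV" if diameter_nm < SV_GV_BOUNDARY_NM else "GV"


def assign_distances(
    scene: SynapseScene, docked_max_nm: float = DOCKED_MAX_GAP_NM
) -> pd.DataFrame:
    """Per-vesicle records: class, nearest-AZ gap distance, docked flag.

    The membrane-to-membrane gap is the center-to-surface distance minus
    the vesicle radius, clamped at 0; the raw signed value is kept for QC.
    """
    if not scene.az_meshes:
        raise ValueError("no AZ mesh in scene")
    ves = scene.vesicles
    records = []
    centers = ves[["x", "y", "z"]].to_numpy(dtype=float)
    radii = ves["diameter_nm"].to_numpy(dtype=float) / 2.0
    dist_per_az = np.column_stack(
        [points_to_mesh_distance(centers, m) for m in scene.az_meshes]
    ) if len(ves) else np.empty((0, len(scene.az_meshes)))
    for i, v in enumerate(ves.itertuples()):
        center_d = dist_per_az[i]
        j = int(np.argmin(center_d))
        raw = float(center_d[j] - radii[i])
        gap = max(raw, 0.0)
        records.append(
            dict(
                vesicle_id=v.vesicle_id,
                diameter_nm=v.diameter_nm,
                dense_core=bool(v.dense_core),
                vesicle_class=classify_vesicle(v.diameter_nm, v.dense_core),
                distance_nm=gap,
                raw_distance_nm=raw,
                nearest_az=j,
                docked=bool(gap <= docked_max_nm),
            )
        )
    return pd.DataFrame(
        records,
        columns=[
            "vesicle_id", "diameter_nm", "dense_core", "vesicle_class",
            "distance_nm", "raw_distance_nm", "nearest_az", "docked",
        ],
    )


def density_profile_3d(
    records: pd.DataFrame,
    az_area_nm2: float,
    bins: BinScheme | None = None,
    az_id: object = 0,
) -> AZDensityProfile:
    """Binned vesicle counts normalized to AZ area (densities in um^-2)."""
    if az_area_nm2 <= 0:
        raise ValueError("AZ area must be > 0")
    bins = bins or BinScheme()
    area_um2 = az_area_nm2 / 1e6
    counts = {}
    for cls in ("SV", "GV"):
        sub = records[records["vesicle_class"] == cls]
        idx = bins.assign(sub["distance_nm"].to_numpy())
        counts[cls] = np.array(
            [int((idx == b).sum()) for b in range(bins.n_bins)]
        )
    gv = records[records["vesicle_class"] == "GV"]
    gv_window = gv[gv["distance_nm"] <= GV_WINDOW_NM]
    docked_gv = int(gv_window["docked"].sum())
    return AZDensityProfile(
        az_id=az_id,
        denominator=az_area_nm2,
        dimension="3D",
        edges=bins.edges,
        counts_sv=counts["SV"],
        counts_gv=counts["GV"],
        density_sv=counts["SV"] / area_um2,
        density_gv=counts["GV"] / area_um2,
        docked_gv_count=docked_gv,
        gv_within_window=len(gv_window),
    )


def include_az_2d(profile, max_tilt_deg: float = 30.0) -> bool:
    """Clear-cut membrane rule: keep AZ profiles that stay near-perpendicular
    to the section plane (surface tilt below the threshold all along)."""
    tilts = np.asarray(profile.segment_tilt_deg, dtype=float)
    return bool(np.all(tilts <= max_tilt_deg))


def density_profile_2d(
    profile: SectionProfile2D,
    bins: tuple[float, ...] = (0.0, 5.0, 10.0),
    max_tilt_deg: float = 30.0,
) -> list[AZDensityProfile]:
    """Per-AZ-profile densities per 100 nm of AZ length (bins 0-5, 5-10 nm).

    AZ profiles failing the inclusion rule are returned with
    ``skipped=True`` and NaN densities.  ``extra`` carries the proportion
    of 0-10-nm vesicles lying within 0-5 nm and the has-vesicle flag.
    """
    scheme = BinScheme(edges=tuple(bins))
    results = []
    ves = profile.vesicles
    for az in profile.az_profiles:
        line: PolyLine2D = az.polyline
        length = line.length
        if not include_az_2d(az, max_tilt_deg):
            results.append(
                AZDensityProfile(
                    az_id=az.az_id, denominator=length, dimension="2D",
                    edges=scheme.edges,
                    counts_sv=np.zeros(scheme.n_bins, dtype=int),
                    counts_gv=np.zeros(scheme.n_bins, dtype=int),
                    density_sv=np.full(scheme.n_bins, np.nan),
                    density_gv=np.full(scheme.n_bins, np.nan),
                    skipped=True,
                )
            )
            continue
        dists = []
        classes = []
        for v in ves.itertuples():
            gap = point_to_polyline_distance(
                np.array([v.u, v.z]), line
            ) - v.apparent_diameter_nm / 2.0
            dists.append(max(gap, 0.0))
            classes.append(classify_vesicle(v.apparent_diameter_nm, False))
        dists = np.asarray(dists)
        classes = np.asarray(classes) if classes else np.empty(0, dtype=object)
        idx = scheme.assign(dists) if len(dists) else np.empty(0, dtype=int)
        counts = {
            cls: np.array(
                [int(((idx == b) & (classes == cls)).sum()) for b in range(scheme.n_bins)]
            )
            for cls in ("SV", "GV")
        }
        per100 = 100.0 / length
        n_within_10 = int((idx >= 0).sum())
        n_within_5 = int((idx == 0).sum()) if scheme.edges[1] == 5.0 else None
        extra = {
            "has_vesicle_within_outer": n_within_10 > 0,
            "frac_0_5_of_0_10": (
                n_within_5 / n_within_10 if (n_within_5 is not None and n_within_10) else np.nan
            ),
        }
        results.append(
            AZDensityProfile(
                az_id=az.az_id, denominator=length, dimension="2D",
                edges=scheme.edges,
                counts_sv=counts["SV"], counts_gv=counts["GV"],
                density_sv=counts["SV"] * per100,
                density_gv=counts["GV"] * per100,
                extra=extra,
            )
        )
    return results


def normalize_to_control(
    table: pd.DataFrame,
    metrics: list[str],
    condition_col: str = "condition",
    control: str = "NS",
) -> pd.DataFrame:
    """Divide per-AZ metrics by the control-condition mean of each metric.

    The control mean maps to 1.0 by construction.
    """
    if control not in set(table[condition_col]):
        raise ValueError(f"control condition {control!r} missing")
    out = table.copy()
    ctrl = table[table[condition_col] == control]
    for m in metrics:
        mu = ctrl[m].mean()
        if not np.isfinite(mu) or mu == 0:
            raise ValueError(f"degenerate control: mean of {m!r} is 0 or undefined")
        out[m + "_norm"] = table[m] / mu
    non_control = out[out[condition_col] != control]
    if len(non_control) == 0 and len(set(table[condition_col])) > 1:
        warnings.warn("no rows outside the control condition")
    return out
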