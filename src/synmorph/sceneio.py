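"""Scene bundles on disk.

A scene bundle is a directory of standard, tool-agnostic files:

* ``az_<k>.ply``, ``pit_<k>.ply``, ``membrane.ply`` — ascii PLY meshes;
* ``<name>.valid.csv`` — optional per-face validity table (missing wedge);
* ``vesicles.csv`` — vesicle_id, x, y, z, diameter_nm, dense_core;
* ``pits.csv`` — pit_id, radius_nm, pore_radius_nm, neck_length_nm,
  pore_x, pore_y, coated;
* ``truth_vesicles.csv`` / ``truth_pits.csv`` — generator ground truth;
* ``scene.json`` — spec, seed, condition, AZ parameters.

Real segmented data can be dropped into the same schema.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import TriangleMesh
from .synthetic import PitModel, SceneSpec, SynapseScene

__all__ = ["save_scene", "load_scene"]

_FLOAT_FMT = "%.6f"


def _write_mesh(mesh: TriangleMesh, path: Path) -> None:
    mesh.to_trimesh().export(path, file_type="ply", encoding="ascii")
    if mesh.face_valid is not None:
        pd.DataFrame({"face_valid": mesh.face_valid.astype(int)}).to_csv(
            path.with_suffix(".valid.csv"), index=False
        )


def _read_mesh(path: Path) -> TriangleMesh:
    valid_path = path.with_suffix(".valid.csv")
    valid = None
    if valid_path.exists():
        valid = pd.read_csv(valid_path)["face_valid"].to_numpy(dtype=bool)
    return TriangleMesh.load(path, face_valid=valid)


def save_scene(scene: SynapseScene, directory) -> Path:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    for k, mesh in enumerate(scene.az_meshes):
        _write_mesh(mesh, d / f"az_{k:02d}.ply")
    for k, mesh in enumerate(scene.pit_meshes):
        _write_mesh(mesh, d / f"pit_{k:02d}.ply")
    _write_mesh(scene.membrane, d / "membrane.ply")
    scene.vesicles[
        ["vesicle_id", "x", "y", "z", "diameter_nm", "dense_core"]
    ].to_csv(d / "vesicles.csv", index=False, float_format=_FLOAT_FMT)
    pd.DataFrame(
        [
            dict(
                pit_id=k, radius_nm=p.radius_nm, pore_radius_nm=p.pore_radius_nm,
                neck_length_nm=p.neck_length_nm, pore_x=p.pore_center[0],
                pore_y=p.pore_center[1], coated=p.coated,
            )
            for k, p in enumerate(scene.pits)
        ],
        columns=["pit_id", "radius_nm", "pore_radius_nm", "neck_length_nm",
                 "pore_x", "pore_y", "coated"],
    ).to_csv(d / "pits.csv", index=False, float_format=_FLOAT_FMT)
    scene.vesicles.to_csv(d / "truth_vesicles.csv", index=False, float_format=_FLOAT_FMT)
    scene.pit_truth.to_csv(d / "truth_pits.csv", index=False, float_format=_FLOAT_FMT)
    meta = {
        "bouton_id": scene.bouton_id,
        "condition": scene.condition,
        "seed": scene.seed,
        "az_params": scene.az_params.to_dict(orient="records"),
        "spec": _spec_dict(scene.spec),
    }
    (d / "scene.json").write_text(json.dumps(meta, indent=2, sort_keys=True, default=_json_default))
    return d


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def _spec_dict(spec: SceneSpec | None):
    if spec is None:
        return None
    d = dataclasses.asdict(spec)
    for k, v in d.items():
        if isinstance(v, float) and math.isinf(v):
            d[k] = "inf"
        elif isinstance(v, tuple):
            d[k] = list(v)
    return d


def _spec_from_dict(d) -> SceneSpec | None:
    if d is None:
        return None
    kw = {}
    for f in dataclasses.fields(SceneSpec):
        if f.name not in d:
            continue
        v = d[f.name]
        if v == "inf":
            v = math.inf
        elif isinstance(v, list):
            v = tuple(v)
        kw[f.name] = v
    return SceneSpec(**kw)


def load_scene(directory) -> SynapseScene:
    d = Path(directory)
    meta = json.loads((d / "scene.json").read_text())
    az_meshes = [_read_mesh(p) for p in sorted(d.glob("az_*.ply"))]
    pit_meshes = [_read_mesh(p) for p in sorted(d.glob("pit_*.ply"))]
    membrane = _read_mesh(d / "membrane.ply")
    vesicles = pd.read_csv(d / "truth_vesicles.csv") if (d / "truth_vesicles.csv").exists() else pd.read_csv(d / "vesicles.csv")
    pits_df = pd.read_csv(d / "pits.csv")
    pits = [
        PitModel(
            radius_nm=r.radius_nm, pore_radius_nm=r.pore_radius_nm,
            neck_length_nm=r.neck_length_nm, pore_center=(r.pore_x, r.pore_y),
            coated=bool(r.coated),
        )
        for r in pits_df.itertuples()
    ]
    pit_truth = pd.read_csv(d / "truth_pits.csv")
    az_params = pd.DataFrame(meta["az_params"])
    return SynapseScene(
        bouton_id=meta["bouton_id"], condition=meta["condition"], seed=meta["seed"],
        az_meshes=az_meshes, az_params=az_params, membrane=membrane,
        vesicles=vesicles, pits=pits, pit_meshes=pit_meshes,
        pit_truth=pit_truth, spec=_spec_from_dict(meta.get("spec")),
    )
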