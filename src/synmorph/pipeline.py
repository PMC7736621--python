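"""End-to-end pipeline: simulate -> measure -> normalize -> compare.

A run is configured by a plain dict (typically loaded from YAML/JSON):

.. code-block:: yaml

    seed: 1
    conditions:
      NS: {n_boutons: 25}
      ST: {n_boutons: 25}
      S:  {n_boutons: 25, docked_fraction: 0.18}
    scene: {n_sv: 30, docked_fraction: 0.30, pit_rate: 2.0}
    wedge: {tilt_range_deg: 60}        # optional missing-wedge occlusion
    analyses: [vesicles3d, pits, stats]
    normalize: true
    control: NS
    metrics: [docked_sv_density]

Per-condition entries override the shared ``scene`` block, which overrides
the SceneSpec defaults.  All randomness derives from the single top-level
seed via spawned child seeds, so outputs are byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .nuclei import quantify_positivity
from .pits import (
    classify_pit,
    filter_census,
    measure_pit,
    pit_surface_area,
    sv_equivalents,
    zone_pit,
)
from .stats import StatsResult, compare_conditions
from .synthetic import (
    NucleiImageSpec,
    SceneSpec,
    SynapseScene,
    WedgeSpec,
    apply_missing_wedge,
    generate_scene,
    section_scene,
)
from .vesicles import (
    BinScheme,
    assign_distances,
    density_profile_2d,
    density_profile_3d,
    normalize_to_control,
)

__all__ = [
    "simulate_conditions",
    "analyze_vesicles_3d",
    "analyze_vesicles_2d",
    "analyze_pits",
    "run_metric_stats",
    "run_pipeline",
]

_FLOAT_FMT = "%.6f"


def _child_seed(seq: np.random.SeedSequence) -> int:
    return int(seq.generate_state(1)[0] % (2**31))


def simulate_conditions(config: dict) -> dict[str, list[SynapseScene]]:
    """Generate per-condition scene lists from a pipeline config."""
    base = dict(config.get("scene", {}))
    conditions = config.get("conditions")
    if not conditions:
        raise ValueError("config has no conditions")
    root = np.random.SeedSequence(int(config.get("seed", 0)))
    out: dict[str, list[SynapseScene]] = {}
    cond_seqs = root.spawn(len(conditions))
    for (name, cfg), cseq in zip(conditions.items(), cond_seqs):
        cfg = dict(cfg or {})
        n_boutons = int(cfg.pop("n_boutons", 1))
        scenes = []
        for b, bseq in enumerate(cseq.spawn(n_boutons)):
            kw = dict(base)
            kw.update(cfg)
            kw.update(
                seed=_child_seed(bseq), condition=name,
                bouton_id=f"{name}-{b:03d}",
            )
            scenes.append(generate_scene(SceneSpec(**kw)))
        out[name] = scenes
    return out


def analyze_vesicles_3d(
    scenes: list[SynapseScene],
    docked_max_nm: float = 2.0,
    bins: BinScheme | None = None,
) -> pd.DataFrame:
    """Per-AZ 3D density table across scenes (one row per AZ)."""
    bins = bins or BinScheme()
    rows = []
    for scene in scenes:
        records = assign_distances(scene, docked_max_nm=docked_max_nm)
        for az in scene.az_params.itertuples():
            sub = records[records["nearest_az"] == az.az_id]
            prof = density_profile_3d(sub, az.area_nm2, bins=bins, az_id=az.az_id)
            row = dict(
                condition=scene.condition, bouton_id=scene.bouton_id,
                az_id=az.az_id, az_area_nm2=az.area_nm2,
                docked_sv_count=int(prof.counts_sv[0]),
                docked_sv_density=float(prof.density_sv[0]),
                docked_gv_density=float(prof.density_gv[0]),
                docked_gv_fraction=prof.docked_gv_fraction,
                total_sv_within_outer=int(prof.counts_sv.sum()),
            )
            for b in range(bins.n_bins):
                lo, hi = bins.edges[b], bins.edges[b + 1]
                row[f"sv_density_{lo:g}_{hi:g}"] = float(prof.density_sv[b])
            # cumulative windows the study reports (0-5, 0-10, 0-40 nm)
            cum = np.cumsum(prof.density_sv)
            for edge_idx, label in ((1, "0_5"), (2, "0_10"), (3, "0_40")):
                if edge_idx < len(cum):
                    row[f"sv_density_{label}"] = float(cum[edge_idx])
            rows.append(row)
    return pd.DataFrame(rows)


def analyze_vesicles_2d(
    scenes: list[SynapseScene],
    thickness_nm: float = 60.0,
    max_tilt_deg: float = 30.0,
) -> pd.DataFrame:
    """One centered ultrathin section per scene, per-AZ-profile densities."""
    rows = []
    for scene in scenes:
        profile = section_scene(scene, thickness_nm, offset_nm=-thickness_nm / 2.0)
        for prof in density_profile_2d(profile, max_tilt_deg=max_tilt_deg):
            rows.append(
                dict(
                    condition=scene.condition, bouton_id=scene.bouton_id,
                    az_id=prof.az_id, az_length_nm=prof.denominator,
                    skipped=prof.skipped,
                    density_0_5_per100=float(prof.density_sv[0] + prof.density_gv[0]),
                    density_0_10_per100=float(
                        np.nansum(prof.density_sv) + np.nansum(prof.density_gv)
                    ) if not prof.skipped else np.nan,
                    frac_0_5_of_0_10=prof.extra.get("frac_0_5_of_0_10", np.nan),
                    has_vesicle=prof.extra.get("has_vesicle_within_outer", False),
                )
            )
    return pd.DataFrame(rows)


def analyze_pits(
    scenes: list[SynapseScene],
    wedge: WedgeSpec | None = None,
    d_sv_nm: float = 46.0,
) -> pd.DataFrame:
    """Measure, classify, zone and size every pit in the scenes."""
    rows = []
    for scene in scenes:
        sc = apply_missing_wedge(scene, wedge) if wedge is not None else scene
        for k, mesh in enumerate(sc.pit_meshes):
            pit = sc.pits[k]
            m = measure_pit(mesh, pit_id=k)
            cls, budding = classify_pit(m.D_nm, m.P_nm)
            area = pit_surface_area(mesh)
            sv_raw, sv_round = sv_equivalents(area, d_sv_nm)
            zone, d_az = zone_pit(pit.pore_center, sc.az_meshes)
            rows.append(
                dict(
                    condition=scene.condition, bouton_id=scene.bouton_id,
                    pit_id=k, D_nm=m.D_nm, I_nm=m.I_nm, P_nm=m.P_nm,
                    ratio=m.D_nm / m.P_nm, shape_class=cls, near_budding=budding,
                    area_nm2=area, sv_equivalents=sv_raw,
                    sv_equivalents_rounded=sv_round,
                    az_edge_distance_nm=d_az, zone=zone, coated=pit.coated,
                )
            )
    cols = ["condition", "bouton_id", "pit_id", "D_nm", "I_nm", "P_nm",
            "ratio", "shape_class", "near_budding", "area_nm2",
            "sv_equivalents", "sv_equivalents_rounded",
            "az_edge_distance_nm", "zone", "coated"]
    return pd.DataFrame(rows, columns=cols)


def run_metric_stats(
    table: pd.DataFrame, metrics: list[str], condition_col: str = "condition",
    equal_var: bool = False, lilliefors: bool = False,
) -> dict[str, StatsResult]:
    out = {}
    for m in metrics:
        groups = {
            str(name): sub[m].dropna().to_numpy()
            for name, sub in table.groupby(condition_col)
        }
        out[m] = compare_conditions(
            groups, metric=m, equal_var=equal_var, lilliefors=lilliefors
        )
    return out


def _stats_to_dict(res: StatsResult) -> dict:
    return {
        "metric": res.metric,
        "branch": res.branch,
        "omnibus": {
            "name": res.omnibus_name,
            "statistic": res.omnibus_statistic,
            "p": res.omnibus_p,
        },
        "gate_p": res.gate_p,
        "pairwise": [dataclasses.asdict(c) for c in res.pairwise],
    }


def run_pipeline(config: dict, outdir) -> dict:
    """Execute the configured analyses and write the report bundle.

    Writes per-AZ / per-pit CSVs, a stats JSON, and a manifest recording
    the config, seed and software version.  Returns the summary dict.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    analyses = config.get("analyses", ["vesicles3d", "stats"])
    control = config.get("control", "NS")
    log_lines = [f"synmorph {__version__} pipeline run, seed={config.get('seed', 0)}"]
    summary: dict = {"seed": config.get("seed", 0), "version": __version__}

    scenes_by_cond = simulate_conditions(config)
    log_lines.append(
        "simulated: " + ", ".join(f"{k}({len(v)})" for k, v in scenes_by_cond.items())
    )
    all_scenes = [s for lst in scenes_by_cond.values() for s in lst]
    wedge = WedgeSpec(**config["wedge"]) if "wedge" in config else None

    per_az = None
    if "vesicles3d" in analyses:
        per_az = analyze_vesicles_3d(
            all_scenes, docked_max_nm=float(config.get("docked_max_nm", 2.0))
        )
        if config.get("normalize", True):
            metrics = config.get("metrics", ["docked_sv_density"])
            per_az = normalize_to_control(per_az, metrics, control=control)
        per_az.to_csv(outdir / "per_az_3d.csv", index=False, float_format=_FLOAT_FMT)
        summary["n_az_3d"] = len(per_az)
        log_lines.append(f"vesicles3d: {len(per_az)} AZs")

    if "vesicles2d" in analyses:
        per_az_2d = analyze_vesicles_2d(
            all_scenes, thickness_nm=float(config.get("section_thickness_nm", 60.0))
        )
        per_az_2d.to_csv(outdir / "per_az_2d.csv", index=False, float_format=_FLOAT_FMT)
        summary["n_az_2d"] = len(per_az_2d)
        log_lines.append(f"vesicles2d: {len(per_az_2d)} AZ profiles")

    if "pits" in analyses:
        pit_table = analyze_pits(all_scenes, wedge=wedge)
        pit_table.to_csv(outdir / "pits_morphometry.csv", index=False, float_format=_FLOAT_FMT)
        census = filter_census(pit_table) if len(pit_table) else None
        summary["n_pits"] = len(pit_table)
        if census is not None:
            summary["pit_incidence_noncoated"] = census.incidence_noncoated
            summary["pit_incidence_coated"] = census.incidence_coated
        log_lines.append(f"pits: {len(pit_table)} events")

    if "cre" in analyses:
        from .synthetic import generate_nuclei_image

        spec = NucleiImageSpec(
            seed=int(config.get("seed", 0)), **config.get("nuclei", {})
        )
        img, truth, region = generate_nuclei_image(spec)
        nuclei, res = quantify_positivity(img, region)
        nuclei.to_csv(outdir / "nuclei.csv", index=False, float_format=_FLOAT_FMT)
        summary["cre_positive_fraction"] = res.positive_fraction
        summary["cre_threshold"] = res.threshold
        log_lines.append(
            f"cre: {res.n_positive}/{res.n_target} positive "
            f"({100 * res.positive_fraction:.1f}%)"
        )

    if "stats" in analyses and per_az is not None:
        metrics = config.get("metrics", ["docked_sv_density"])
        results = run_metric_stats(
            per_az, metrics,
            equal_var=bool(config.get("equal_var", False)),
            lilliefors=bool(config.get("lilliefors", False)),
        )
        stats_dict = {m: _stats_to_dict(r) for m, r in results.items()}
        (outdir / "stats.json").write_text(
            json.dumps(stats_dict, indent=2, sort_keys=True)
        )
        summary["stats"] = stats_dict
        for m, r in results.items():
            log_lines.append(
                f"stats[{m}]: {r.branch}, omnibus p={r.omnibus_p:.4g}, "
                + "; ".join(
                    f"{c.group_a} vs {c.group_b}: p_adj={c.p_adjusted:.4g} {c.stars}"
                    for c in r.pairwise
                )
            )

    manifest = {"config": _jsonable(config), "seed": config.get("seed", 0),
                "version": __version__}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    return summary


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
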