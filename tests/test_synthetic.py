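"""Generator ground truth, missing wedge, sectioning, and nuclei images."""

import math

import numpy as np
import pandas as pd
import pytest

from synmorph.geometry import mesh_area
from synmorph.pits import measure_pit
from synmorph.synthetic import (
    NucleiImageSpec,
    PitModel,
    SceneSpec,
    WedgeSpec,
    generate_nuclei_image,
    generate_scene,
    occlude_mesh,
    section_scene,
)


class TestSceneGeneration:
    def test_empty_spec_gives_az_only(self):
        scene = generate_scene(SceneSpec(seed=1, n_sv=0, n_gv=0, n_dcv=0, pit_rate=0.0))
        assert len(scene.vesicles) == 0
        assert len(scene.pits) == 0
        assert len(scene.az_meshes) == 1

    def test_pit_closed_form(self):
        pit = PitModel(radius_nm=44.7, pore_radius_nm=23.0, neck_length_nm=0.0)
        assert pit.true_D == pytest.approx(89.4)
        assert pit.true_P == pytest.approx(46.0)
        assert pit.true_I == pytest.approx(
            44.7 + math.sqrt(44.7**2 - 23.0**2), abs=1e-9
        )
        assert pit.true_I == pytest.approx(83.0, abs=0.05)

    def test_same_seed_identical(self):
        a = generate_scene(SceneSpec(seed=9, pit_rate=2.0))
        b = generate_scene(SceneSpec(seed=9, pit_rate=2.0))
        pd.testing.assert_frame_equal(a.vesicles, b.vesicles)
        pd.testing.assert_frame_equal(a.pit_truth, b.pit_truth)
        for ma, mb in zip(a.pit_meshes, b.pit_meshes):
            assert np.array_equal(ma.vertices, mb.vertices)

    def test_truth_self_consistent_with_geometry(self, small_scene):
        """Re-measuring generated pit meshes reproduces the parametric truth."""
        edge = small_scene.spec.mesh_edge_nm
        for k, mesh in enumerate(small_scene.pit_meshes):
            pit = small_scene.pits[k]
            m = measure_pit(mesh, pit_id=k)
            assert m.D_nm == pytest.approx(pit.true_D, abs=2 * edge)
            assert m.P_nm == pytest.approx(pit.true_P, abs=2 * edge)
            assert m.I_nm == pytest.approx(pit.true_I, abs=2 * edge)
            assert mesh_area(mesh) == pytest.approx(pit.true_area, rel=0.02)

    def test_docked_gap_within_range(self, small_scene):
        docked = small_scene.vesicles[small_scene.vesicles.true_docked]
        assert len(docked) > 0
        assert (docked.true_distance_nm >= 0).all()
        assert (docked.true_distance_nm <= 2.0).all()

    def test_invalid_specs_error(self):
        with pytest.raises(ValueError):
            SceneSpec(n_sv=-1).validate()
        with pytest.raises(ValueError):
            SceneSpec(pit_pore_ratio_range=(0.5, 1.2)).validate()
        with pytest.raises(ValueError):
            PitModel(radius_nm=20.0, pore_radius_nm=25.0, neck_length_nm=0.0)


class TestMissingWedge:
    def test_full_tilt_range_occludes_nothing(self):
        import trimesh

        from synmorph.geometry import TriangleMesh

        sphere = TriangleMesh.from_trimesh(trimesh.creation.icosphere(3, 40.0))
        out = occlude_mesh(sphere, WedgeSpec(tilt_range_deg=90.0))
        assert out.valid_mask().all()

    def test_sphere_occluded_fraction_matches_zone_area(self):
        import trimesh

        from synmorph.geometry import TriangleMesh

        sphere = TriangleMesh.from_trimesh(trimesh.creation.icosphere(4, 40.0))
        out = occlude_mesh(sphere, WedgeSpec(tilt_range_deg=60.0))
        occluded = mesh_area(out) - mesh_area(out, valid_only=True)
        frac = occluded / mesh_area(out)
        # two polar caps: fraction = 1 - cos(30 deg)
        assert frac == pytest.approx(1 - math.cos(math.radians(30.0)), rel=0.02)

    def test_planar_az_normal_along_beam_fully_occluded(self):
        from synmorph.synthetic import disk_mesh

        disk = disk_mesh(50.0, 10.0)
        out = occlude_mesh(disk, WedgeSpec(tilt_range_deg=60.0))
        assert not out.valid_mask().any()

    def test_wedge_validation(self):
        with pytest.raises(ValueError):
            WedgeSpec(tilt_range_deg=0.0)
        with pytest.raises(ValueError):
            WedgeSpec(tilt_range_deg=91.0)


class TestSectioning:
    def test_equatorial_cut_full_diameter(self):
        scene = generate_scene(SceneSpec(seed=2, n_sv=0, n_gv=0, n_dcv=0))
        scene.vesicles = pd.DataFrame(
            [dict(vesicle_id=0, x=0.0, y=0.0, z=40.0, diameter_nm=46.0,
                  dense_core=False, true_class="SV", true_distance_nm=17.0,
                  true_docked=False, az_id=0)]
        )
        sec = section_scene(scene, 60.0, offset_nm=-30.0)
        assert sec.vesicles.apparent_diameter_nm.iloc[0] == pytest.approx(46.0)

    def test_tangent_sphere_excluded(self):
        scene = generate_scene(SceneSpec(seed=2, n_sv=0, n_gv=0, n_dcv=0))
        scene.vesicles = pd.DataFrame(
            [dict(vesicle_id=0, x=83.0, y=0.0, z=40.0, diameter_nm=46.0,
                  dense_core=False, true_class="SV", true_distance_nm=17.0,
                  true_docked=False, az_id=0)]
        )  # center 23 nm beyond the slab edge at x=60
        sec = section_scene(scene, 60.0, offset_nm=0.0)
        assert len(sec.vesicles) == 0

    def test_apparent_never_exceeds_true(self, small_scene, rng):
        for _ in range(50):
            off = rng.uniform(-300, 300)
            sec = section_scene(small_scene, 60.0, off)
            if len(sec.vesicles):
                assert (
                    sec.vesicles.apparent_diameter_nm
                    <= sec.vesicles.true_diameter_nm + 1e-9
                ).all()

    def test_tiling_sees_every_vesicle(self, small_scene):
        seen = np.zeros(len(small_scene.vesicles))
        lo = small_scene.vesicles.x.min() - 60
        hi = small_scene.vesicles.x.max() + 60
        for off in np.arange(lo, hi, 60.0):
            sec = section_scene(small_scene, 60.0, off)
            for v in sec.vesicles.itertuples():
                seen[int(v.vesicle_id)] += 1
        assert (seen >= 1).all()

    def test_empty_slab_is_empty_not_error(self, small_scene):
        sec = section_scene(small_scene, 60.0, offset_nm=5000.0)
        assert len(sec.vesicles) == 0
        assert len(sec.az_profiles) == 0

    def test_bad_thickness(self, small_scene):
        with pytest.raises(ValueError):
            section_scene(small_scene, 0.0, 0.0)


class TestNucleiImages:
    def test_zero_nuclei_background_only(self):
        spec = NucleiImageSpec(seed=0, n_target=0, n_background=0, noise_sd=0.0)
        img, truth, _ = generate_nuclei_image(spec)
        assert len(truth) == 0
        assert np.allclose(img, spec.background_intensity, atol=0.5)

    def test_same_seed_identical_bytes(self):
        a, _, _ = generate_nuclei_image(NucleiImageSpec(seed=5))
        b, _, _ = generate_nuclei_image(NucleiImageSpec(seed=5))
        assert a.tobytes() == b.tobytes()

    def test_true_positive_count_matches_fraction(self):
        spec = NucleiImageSpec(seed=3, n_target=80, positive_fraction=0.912)
        _, truth, _ = generate_nuclei_image(spec)
        target = truth[truth.region == "target"]
        assert target.true_positive.sum() == round(0.912 * 80)

    def test_infeasible_count_errors(self):
        with pytest.raises(ValueError, match="infeasible"):
            generate_nuclei_image(NucleiImageSpec(seed=0, shape=(64, 64), n_target=500))

    def test_intensity_out_of_depth_errors(self):
        with pytest.raises(ValueError):
            generate_nuclei_image(NucleiImageSpec(positive_mean=5000.0))

    def test_tiff_roundtrip(self, tmp_path):
        from synmorph.synthetic import load_nuclei_image, save_nuclei_image

        img, _, _ = generate_nuclei_image(
            NucleiImageSpec(seed=1, n_target=10, n_background=4)
        )
        save_nuclei_image(img, tmp_path / "i.tif")
        assert np.array_equal(load_nuclei_image(tmp_path / "i.tif"), img)
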