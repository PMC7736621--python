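"""Omega-pit morphometry: D/I/P, classes, areas, zoning, census filters."""

import math

import numpy as np
import pandas as pd
import pytest

from synmorph.geometry import mesh_area
from synmorph.pits import (
    classify_pit,
    filter_census,
    measure_pit,
    measure_pit_2d,
    pit_surface_area,
    sv_equivalents,
    zone_pit,
)
from synmorph.synthetic import (
    PitModel,
    SceneSpec,
    WedgeSpec,
    disk_mesh,
    generate_scene,
    occlude_mesh,
    section_scene,
)


class TestMeasurePit:
    def test_reference_pit_closed_form(self, reference_pit):
        m = measure_pit(reference_pit.mesh(2.0))
        assert m.D_nm == pytest.approx(89.4, abs=4.0)
        assert m.P_nm == pytest.approx(46.0, abs=4.0)
        assert m.I_nm == pytest.approx(83.0, abs=4.0)

    def test_hemispherical_cap(self):
        pit = PitModel(radius_nm=30.0, pore_radius_nm=30.0, neck_length_nm=0.0)
        m = measure_pit(pit.mesh(1.0))
        assert m.D_nm == pytest.approx(60.0, abs=2.0)
        assert m.P_nm == pytest.approx(60.0, abs=2.0)
        assert m.I_nm == pytest.approx(30.0, abs=2.0)
        cls, budding = classify_pit(m.D_nm, m.P_nm)
        assert cls == "EQ1"
        assert not budding

    def test_open_surface_without_pore_errors(self):
        pit = PitModel(radius_nm=30.0, pore_radius_nm=15.0, neck_length_nm=0.0)
        mesh = pit.mesh(2.0)
        mesh.vertices = mesh.vertices + np.array([0.0, 0.0, 50.0])  # float it
        with pytest.raises(ValueError, match="pore"):
            measure_pit(mesh)

    def test_rigid_motion_invariance(self, reference_pit, rng):
        mesh = reference_pit.mesh(2.0)
        m0 = measure_pit(mesh)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        t = rng.normal(size=3) * 100
        moved = mesh.transformed(q, t)
        m1 = measure_pit(
            moved, membrane_origin=t, membrane_normal=q @ np.array([0.0, 0.0, 1.0])
        )
        assert m1.D_nm == pytest.approx(m0.D_nm, abs=0.5)
        assert m1.I_nm == pytest.approx(m0.I_nm, abs=0.5)
        assert m1.P_nm == pytest.approx(m0.P_nm, abs=0.5)

    def test_2d_section_underestimates(self, reference_pit):
        scene = generate_scene(SceneSpec(seed=5, n_sv=0, n_gv=0, n_dcv=0))
        scene.pits = [PitModel(44.7, 23.0, 10.0, pore_center=(300.0, 0.0))]
        scene.pit_meshes = [scene.pits[0].mesh(2.0)]
        pit = scene.pits[0]
        for mid_off in (5.0, 12.0, 20.0):
            sec = section_scene(scene, 60.0, 300.0 + mid_off - 30.0)
            for pp in sec.pit_profiles:
                m2 = measure_pit_2d(pp.contour)
                assert m2.dimension == "2D"
                assert m2.D_nm <= pit.true_D + 1e-6
                assert m2.I_nm <= pit.true_I + 1e-6


class TestClassify:
    @pytest.mark.parametrize(
        "D,P,cls,budding",
        [
            (60.0, 60.0, "EQ1", False),
            (62.0, 60.0, "EQ1", False),  # within the 0.05 tolerance band
            (80.0, 60.0, "GT1_1p5", False),
            (90.0, 60.0, "GT1_1p5", False),  # ratio exactly 1.5 stays below
            (90.0, 45.0, "R1p5_2", True),  # ratio exactly 2.0
            (150.0, 40.0, "GT2", True),
            (320.0, 160.0, "R1p5_2", False),  # pore >= 100 nm: not budding
        ],
    )
    def test_classes_and_budding(self, D, P, cls, budding):
        got_cls, got_budding = classify_pit(D, P)
        assert got_cls == cls
        assert got_budding == budding

    def test_inconsistent_measurement(self):
        with pytest.raises(ValueError, match="inconsistent"):
            classify_pit(50.0, 60.0)
        with pytest.raises(ValueError):
            classify_pit(0.0, 10.0)


class TestSurfaceArea:
    def test_unoccluded_equals_mesh_area(self, reference_pit):
        mesh = reference_pit.mesh(2.0)
        assert pit_surface_area(mesh) == mesh_area(mesh)

    def test_wedge_completed_within_five_percent(self):
        for seed, L in ((0, 0.0), (1, 10.0), (2, 25.0)):
            pit = PitModel(40.0 + seed, 20.0, L)
            occluded = occlude_mesh(pit.mesh(2.0), WedgeSpec(60.0))
            assert not occluded.valid_mask().all()
            area = pit_surface_area(occluded)
            assert area == pytest.approx(pit.true_area, rel=0.05)

    def test_too_occluded_errors(self, reference_pit):
        mesh = reference_pit.mesh(2.0)
        mesh.face_valid = np.zeros(len(mesh.faces), dtype=bool)
        mesh.face_valid[: int(0.2 * len(mesh.faces))] = True
        with pytest.raises(ValueError, match="valid"):
            pit_surface_area(mesh)

    def test_degenerate_fit_falls_back_with_warning(self):
        plane = disk_mesh(40.0, 4.0)
        plane.face_valid = np.ones(len(plane.faces), dtype=bool)
        plane.face_valid[::2] = False
        with pytest.warns(UserWarning, match="degenerate"):
            area = pit_surface_area(plane)
        assert area == pytest.approx(mesh_area(plane, valid_only=True))


class TestSvEquivalents:
    def test_unit_area(self):
        raw, rounded = sv_equivalents(math.pi * 46.0**2)
        assert raw == pytest.approx(1.0, abs=1e-12)
        assert rounded == 1

    def test_linearity(self):
        raw, rounded = sv_equivalents(11 * math.pi * 46.0**2)
        assert raw == pytest.approx(11.0, abs=1e-12)
        assert rounded == 11

    def test_reference_diameter_scaling(self):
        area = 5 * math.pi * 46.0**2
        raw1, _ = sv_equivalents(area, 46.0)
        raw2, _ = sv_equivalents(area, 92.0)
        assert raw2 == pytest.approx(raw1 / 4.0)

    def test_rounding_floor(self):
        raw, rounded = sv_equivalents(0.6 * math.pi * 46.0**2)
        assert rounded == 1
        raw, rounded = sv_equivalents(0.3 * math.pi * 46.0**2)
        assert rounded == 0

    def test_errors(self):
        with pytest.raises(ValueError):
            sv_equivalents(0.0)
        with pytest.raises(ValueError):
            sv_equivalents(100.0, 0.0)


class TestZoning:
    def test_peri_vs_distal(self):
        az = disk_mesh(100.0, 10.0)
        zone, d = zone_pit([150.0, 0.0], [az])
        assert zone == "peri_AZ" and d == pytest.approx(50.0, abs=0.5)
        zone, _ = zone_pit([350.0, 0.0], [az])
        assert zone == "distal"
        zone, _ = zone_pit([300.0, 0.0], [az])  # exactly 200: closed boundary
        assert zone == "peri_AZ"

    def test_no_az_errors(self):
        with pytest.raises(ValueError):
            zone_pit([0.0, 0.0], [])


class TestCensus:
    def _pits(self):
        return pd.DataFrame(
            dict(
                bouton_id=["b1", "b1", "b2", "b2", "b2"],
                pit_id=[0, 1, 2, 3, 4],
                coated=[False, True, False, False, False],
                midline_in_volume=[True, True, False, True, True],
                fully_in_volume=[True, False, False, True, True],
            )
        )

    def test_incidence_counts_everything(self):
        census = filter_census(self._pits())
        assert census.n_boutons == 2
        assert census.incidence_coated == pytest.approx(0.5)
        assert census.incidence_noncoated == pytest.approx(2.0)

    def test_morphometry_and_area_filters(self):
        census = filter_census(self._pits())
        assert census.morphometry_ids == [0, 1, 3, 4]
        assert census.area_ids == [0, 3, 4]

    def test_geometric_bounds(self, reference_pit):
        mesh = reference_pit.mesh(4.0)
        pits = pd.DataFrame(
            dict(bouton_id=["b"], pit_id=[0], coated=[False])
        )
        inside = filter_census(
            pits, {0: mesh}, volume_bounds=([-100, -100, -1], [100, 100, 200])
        )
        assert inside.morphometry_ids == [0]
        clipped = filter_census(
            pits, {0: mesh}, volume_bounds=([-100, -100, -1], [100, 100, 50])
        )
        assert clipped.morphometry_ids == []  # deepest point outside bounds
        assert clipped.per_bouton.n_noncoated.sum() == 1  # still in incidence
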