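"""Vesicle classification, distance binning, densities, normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from synmorph.synthetic import SceneSpec, generate_scene, section_scene
from synmorph.vesicles import (
    BinScheme,
    assign_distances,
    classify_vesicle,
    density_profile_2d,
    density_profile_3d,
    include_az_2d,
    normalize_to_control,
)


class TestClassification:
    @pytest.mark.parametrize(
        "diameter,core,expected",
        [
            (46.0, False, "SV"),
            (59.999, False, "SV"),
            (60.0, False, "GV"),  # boundary: "less than 60" is SV
            (61.0, False, "GV"),
            (80.0, True, "DCV"),
            (46.0, True, "DCV"),  # dense core wins regardless of size
        ],
    )
    def test_rules(self, diameter, core, expected):
        assert classify_vesicle(diameter, core) == expected

    def test_nonpositive_diameter_errors(self):
        with pytest.raises(ValueError):
            classify_vesicle(0.0, False)


class TestBinScheme:
    def test_edge_ties_go_to_lower_bin(self):
        b = BinScheme()
        idx = b.assign(np.array([0.0, 1.0, 2.0, 2.0001, 5.0, 100.0, 100.1]))
        assert list(idx) == [0, 0, 0, 1, 1, 5, -1]

    def test_invalid_edges(self):
        with pytest.raises(ValueError):
            BinScheme(edges=(1.0, 2.0))
        with pytest.raises(ValueError):
            BinScheme(edges=(0.0, 5.0, 5.0))

    @given(st.lists(st.floats(0, 120), min_size=1, max_size=60))
    @settings(max_examples=50, deadline=None)
    def test_conservation_and_monotonicity(self, distances):
        b = BinScheme()
        idx = b.assign(np.array(distances))
        counts = np.array([(idx == k).sum() for k in range(b.n_bins)])
        within = sum(1 for d in distances if d <= b.edges[-1])
        assert counts.sum() == within
        assert (np.diff(np.cumsum(counts)) >= 0).all()


class TestDistances:
    def test_recovers_generator_truth(self, small_scene):
        rec = assign_distances(small_scene)
        err = np.abs(
            rec.distance_nm.to_numpy()
            - small_scene.vesicles.true_distance_nm.to_numpy()
        )
        assert err.max() <= 2 * small_scene.spec.mesh_edge_nm
        assert (
            rec.docked.to_numpy() == small_scene.vesicles.true_docked.to_numpy()
        ).all()

    def test_distant_vesicle_kept_in_record(self):
        scene = generate_scene(SceneSpec(seed=4, n_sv=0, n_gv=0, n_dcv=0))
        scene.vesicles = pd.DataFrame(
            [dict(vesicle_id=0, x=0.0, y=0.0, z=173.0, diameter_nm=46.0,
                  dense_core=False, true_class="SV", true_distance_nm=150.0,
                  true_docked=False, az_id=0)]
        )
        rec = assign_distances(scene)
        assert len(rec) == 1
        prof = density_profile_3d(rec, 50_000.0)
        assert prof.counts_sv.sum() == 0  # beyond the 100-nm outer edge

    def test_no_az_errors(self, small_scene):
        import dataclasses

        broken = dataclasses.replace(small_scene, az_meshes=[])
        with pytest.raises(ValueError):
            assign_distances(broken)


class TestDensity3D:
    def test_docked_bin_density(self):
        rec = pd.DataFrame(
            dict(
                vesicle_id=range(5),
                diameter_nm=[46.0] * 5,
                dense_core=[False] * 5,
                vesicle_class=["SV"] * 5,
                distance_nm=[1.0] * 5,
                raw_distance_nm=[1.0] * 5,
                nearest_az=[0] * 5,
                docked=[True] * 5,
            )
        )
        prof = density_profile_3d(rec, az_area_nm2=50_000.0)  # 0.05 um^2
        assert prof.density_sv[0] == pytest.approx(100.0)
        assert prof.counts_sv[1:].sum() == 0

    def test_zero_area_errors(self):
        with pytest.raises(ValueError):
            density_profile_3d(pd.DataFrame(columns=["vesicle_class", "distance_nm", "docked"]), 0.0)

    def test_bin_conservation_on_scene(self, small_scene):
        rec = assign_distances(small_scene)
        prof = density_profile_3d(rec, small_scene.az_areas[0])
        within = rec[(rec.vesicle_class == "SV") & (rec.distance_nm <= 100.0)]
        assert prof.counts_sv.sum() == len(within)


class TestDensity2D:
    def test_two_vesicles_on_200nm_az(self):
        scene = generate_scene(SceneSpec(seed=6, n_sv=0, n_gv=0, n_dcv=0))
        sec = section_scene(scene, 60.0, -30.0)
        # keep a 200-nm stretch: synthesize a controlled profile instead
        from synmorph.geometry import PolyLine2D
        from synmorph.synthetic import AZProfile2D, SectionProfile2D

        prof = SectionProfile2D(
            bouton_id="b", condition="NS", thickness_nm=60.0, offset_nm=0.0,
            az_profiles=[AZProfile2D(0, PolyLine2D([[0.0, 0.0], [200.0, 0.0]]),
                                     np.zeros(1))],
            vesicles=pd.DataFrame(
                dict(vesicle_id=[0, 1], u=[50.0, 150.0], z=[24.0, 25.0],
                     apparent_diameter_nm=[46.0, 46.0],
                     true_diameter_nm=[46.0, 46.0])
            ),
            pit_profiles=[],
        )
        out = density_profile_2d(prof)
        assert out[0].density_sv[0] == pytest.approx(1.0)  # 2 per 200 nm

    def test_empty_profile_counts_az(self):
        from synmorph.geometry import PolyLine2D
        from synmorph.synthetic import AZProfile2D, SectionProfile2D

        prof = SectionProfile2D(
            bouton_id="b", condition="NS", thickness_nm=60.0, offset_nm=0.0,
            az_profiles=[AZProfile2D(0, PolyLine2D([[0.0, 0.0], [150.0, 0.0]]),
                                     np.zeros(1))],
            vesicles=pd.DataFrame(
                columns=["vesicle_id", "u", "z", "apparent_diameter_nm",
                         "true_diameter_nm"]
            ),
            pit_profiles=[],
        )
        out = density_profile_2d(prof)
        assert not out[0].skipped
        assert out[0].density_sv.sum() == 0.0
        assert out[0].extra["has_vesicle_within_outer"] is False


class TestInclusionRule:
    def test_planar_az_included(self):
        scene = generate_scene(SceneSpec(seed=1, n_sv=0, n_gv=0, n_dcv=0))
        sec = section_scene(scene, 60.0, -30.0)
        assert all(include_az_2d(p) for p in sec.az_profiles)

    def test_curved_az_grazing_cut_excluded(self):
        scene = generate_scene(
            SceneSpec(seed=1, az_curvature_radius_nm=100.0, n_sv=0, n_gv=0, n_dcv=0)
        )
        # cut near the lateral pole of the 100-nm spine: high surface tilt
        sec = section_scene(scene, 60.0, offset_nm=60.0)
        assert len(sec.az_profiles) > 0
        assert not all(include_az_2d(p) for p in sec.az_profiles)

    def test_threshold_90_includes_everything(self):
        scene = generate_scene(
            SceneSpec(seed=1, az_curvature_radius_nm=100.0, n_sv=0, n_gv=0, n_dcv=0)
        )
        sec = section_scene(scene, 60.0, offset_nm=60.0)
        assert all(include_az_2d(p, max_tilt_deg=90.0) for p in sec.az_profiles)


class TestNormalization:
    def _table(self):
        return pd.DataFrame(
            dict(
                condition=["NS"] * 4 + ["S"] * 4,
                docked=[10.0, 12.0, 8.0, 10.0, 5.0, 6.0, 4.0, 5.0],
            )
        )

    def test_control_mean_maps_to_one(self):
        out = normalize_to_control(self._table(), ["docked"])
        assert out[out.condition == "NS"].docked_norm.mean() == pytest.approx(1.0)
        assert out[out.condition == "S"].docked_norm.mean() == pytest.approx(0.5)

    def test_missing_control_errors(self):
        t = self._table()
        t = t[t.condition != "NS"]
        with pytest.raises(ValueError, match="control"):
            normalize_to_control(t, ["docked"])

    def test_degenerate_control_errors(self):
        t = self._table()
        t.loc[t.condition == "NS", "docked"] = 0.0
        with pytest.raises(ValueError, match="degenerate"):
            normalize_to_control(t, ["docked"])
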