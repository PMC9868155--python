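"""Plane slicing, constriction location, regions, subsegments, morphometry."""

import numpy as np
import pytest
import shapely.geometry as sg

import pharyngoflow as pf
from pharyngoflow.geometry import (
    OROPHARYNX,
    VELOPHARYNX,
    DiscontinuousLumenError,
    NoConstrictionError,
)


def _sections_from_areas(areas, spacing=0.5):
    n = len(areas)
    return [
        pf.PlaneSection(index=i + 1, z_mm=(n - 1 - i) * spacing, area_mm2=float(a))
        for i, a in enumerate(areas)
    ]


class TestSliceAirway:
    def test_cylinder_plane_count_and_areas(self, cylinder):
        mesh, prof = cylinder
        secs = pf.slice_airway(mesh, 50.0, 0.0, 0.5)
        assert len(secs) == 101
        assert [s.index for s in secs] == list(range(1, 102))
        for s in secs:
            assert s.area_mm2 == pytest.approx(np.pi * 25, rel=0.01)

    def test_disjoint_lumens_are_summed(self, two_lumen_mesh):
        secs = pf.slice_airway(two_lumen_mesh, 15.0, 5.0, 5.0)
        # independent oracle: rasterized point-in-polygon area of both lumens
        paths = two_lumen_mesh.section_multiplane(
            plane_origin=[0, 0, 0], plane_normal=[0, 0, 1], heights=[10.0 + 1e-4]
        )
        polys = [p for p in paths[0].polygons_closed if p is not None]
        xs = np.linspace(-16, 16, 400)
        ys = np.linspace(-8, 8, 200)
        cell = (xs[1] - xs[0]) * (ys[1] - ys[0])
        pts = [sg.Point(x, y) for x in xs for y in ys]
        raster = cell * sum(sum(p.contains(pt) for pt in pts) for p in polys)
        mid = secs[1]
        assert mid.area_mm2 == pytest.approx(50.0, rel=0.01)
        assert mid.area_mm2 == pytest.approx(raster, rel=0.02)

    def test_template_length_gives_printed_plane_count(self, ftp4_mesh, ftp4_profile):
        # 51.2 mm segment at 0.5 mm spacing -> 103 descending planes
        secs = pf.slice_airway(ftp4_mesh, ftp4_profile.z_mm[0], ftp4_profile.z_mm[-1], 0.5)
        assert len(secs) == 103

    def test_plane_outside_mesh_reports_discontinuity(self, cylinder):
        mesh, _ = cylinder
        with pytest.raises(DiscontinuousLumenError, match="z ="):
            pf.slice_airway(mesh, 60.0, -10.0, 5.0)


class TestPlaneAmin:
    def test_unique_minimum(self):
        secs = _sections_from_areas([5, 4, 3, 4, 5])
        assert pf.find_plane_amin(secs) == 3

    def test_plateau_tie_breaks_to_first(self):
        secs = _sections_from_areas([5, 3, 3, 3, 5])
        assert pf.find_plane_amin(secs) == 2

    def test_all_equal_raises_no_constriction(self):
        secs = _sections_from_areas([4, 4, 4, 4])
        with pytest.raises(NoConstrictionError):
            pf.find_plane_amin(secs)

    def test_template_roundtrip_recovers_printed_plane(self, ftp4_mesh, ftp4_profile):
        secs = pf.slice_airway(ftp4_mesh, ftp4_profile.z_mm[0], ftp4_profile.z_mm[-1], 0.5)
        assert abs(pf.find_plane_amin(secs) - 41) <= 1

    def test_regional_search_is_restricted(self, ftp4_mesh, ftp4_profile):
        secs = pf.slice_airway(ftp4_mesh, ftp4_profile.z_mm[0], ftp4_profile.z_mm[-1], 0.5)
        pf.assign_regions(secs, 53)
        oro = pf.find_plane_amin(secs, OROPHARYNX)
        assert oro > 53  # searched only among planes 54..103


class TestRegions:
    def test_partition(self):
        secs = _sections_from_areas(range(10, 0, -1))
        pf.assign_regions(secs, 4)
        assert sum(s.region == VELOPHARYNX for s in secs) == 4
        assert sum(s.region == OROPHARYNX for s in secs) == 6
        # region flips exactly once
        flips = sum(a.region != b.region for a, b in zip(secs, secs[1:]))
        assert flips == 1

    @pytest.mark.parametrize("bad", [1, 10, 11, 0])
    def test_out_of_range_dividing_plane(self, bad):
        secs = _sections_from_areas(range(10, 0, -1))
        with pytest.raises(ValueError):
            pf.assign_regions(secs, bad)


class TestAreaRatios:
    def test_constant_areas_give_unit_ratios(self):
        secs = _sections_from_areas([50.0] * 5)
        assert np.allclose(pf.area_ratio_series(secs), 1.0)

    def test_direct_formula(self):
        secs = _sections_from_areas([100.0, 50.0])
        assert pf.area_ratio_series(secs)[0] == pytest.approx(2.0)

    def test_narrowing_gives_ratios_above_one_upstream_of_amin(self, ftp4_profile):
        secs = _sections_from_areas(ftp4_profile.area_mm2)
        ratios = pf.area_ratio_series(secs)
        i_min = int(np.argmin(ftp4_profile.area_mm2))
        assert np.all(ratios[:i_min] > 1.0)

    def test_ratio_to_amin_variant_is_one_at_constriction(self, ftp4_profile):
        secs = _sections_from_areas(ftp4_profile.area_mm2)
        amin = pf.find_plane_amin(secs)
        r = pf.geometry.area_ratio_to_amin(secs, amin)
        assert r[amin - 1] == pytest.approx(1.0)
        assert np.all(r >= 1.0)


class TestSubsegments:
    def test_count_and_alignment(self):
        secs = _sections_from_areas(np.linspace(100, 50, 103))
        subs = pf.build_subsegments(secs)
        assert len(subs) == 102
        # subsegment N spans planes N and N+1 (e.g. subseg 40 -> planes 40-41)
        assert subs[39].index == 40
        assert subs[39].z_upper_mm == secs[39].z_mm
        assert subs[39].z_lower_mm == secs[40].z_mm

    def test_cylinder_band_wall_area_matches_closed_form(self, cylinder):
        mesh, prof = cylinder
        secs = pf.slice_airway(mesh, 50.0, 0.0, 0.5)
        subs = pf.build_subsegments(secs, mesh)
        expected = 2 * np.pi * 5.0 * 0.5
        areas = np.array([s.wall_area_mm2 for s in subs])
        assert np.all(np.abs(areas - expected) / expected < 0.02)


class TestMorphometry:
    def test_length_follows_gap_convention(self):
        secs = _sections_from_areas(np.linspace(100, 50, 103))
        rep = pf.morphometry_report(secs, 0.5)
        assert rep.segment_length_cm == pytest.approx(5.10)
        assert rep.n_planes == 103

    def test_cylinder_flags_no_constriction(self, cylinder):
        mesh, _ = cylinder
        secs = pf.slice_airway(mesh, 50.0, 0.0, 0.5)
        rep = pf.morphometry_report(secs, 0.5)
        assert rep.regions["all"]["no_constriction"] is True

    def test_template_velopharyngeal_minimum_area(self, ftp4_mesh, ftp4_profile):
        secs = pf.slice_airway(ftp4_mesh, ftp4_profile.z_mm[0], ftp4_profile.z_mm[-1], 0.5)
        pf.assign_regions(secs, 53)
        rep = pf.morphometry_report(secs, 0.5)
        velo = rep.regions[VELOPHARYNX]
        assert velo["amin_area_cm2"] == pytest.approx(0.5443, rel=0.02)
        assert rep.dividing_plane_index == 53


class TestSlicerConvergence:
    def test_area_error_decreases_monotonically_with_refinement(self):
        prof = pf.AreaProfile(
            z_mm=10.0 - 2.0 * np.arange(6), area_mm2=np.full(6, np.pi * 25)
        )
        errs = []
        for n_theta in (16, 32, 64):
            mesh = pf.make_surface_mesh(prof, n_theta=n_theta)
            secs = pf.slice_airway(mesh, 10.0, 0.0, 2.0)
            rel = max(abs(s.area_mm2 - np.pi * 25) / (np.pi * 25) for s in secs)
            errs.append(rel)
        assert errs[0] > errs[1] > errs[2]
        assert errs[2] < 0.01
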