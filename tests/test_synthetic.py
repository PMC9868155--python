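"""Synthetic airway geometry and flow-field generator."""

import numpy as np
import pytest

import pharyngoflow as pf
from pharyngoflow.synthetic import FluxNormalizationError


class TestAreaProfile:
    def test_custom_profile_minimum_at_requested_position(self):
        spec = pf.SyntheticSpec(
            length_mm=50, amin_area_mm2=100, amin_relative_position=0.4,
            expansion_area_mm2=200,
        )
        prof = pf.make_area_profile(spec)
        i_expect = round(0.4 * (prof.n_planes - 1))
        assert prof.area_mm2.min() == pytest.approx(100.0)
        assert int(np.argmin(prof.area_mm2)) == i_expect
        # unique global minimum
        assert np.sum(prof.area_mm2 == prof.area_mm2.min()) == 1

    def test_template_minimum_equals_configured_area(self):
        # narrowest velopharyngeal constriction among the eight morphologies
        spec = pf.SyntheticSpec.from_template("FTP4_MO")
        prof = pf.make_area_profile(spec)
        assert prof.area_mm2.min() == pytest.approx(54.43)
        assert prof.amin_plane == 41
        assert prof.n_planes == 103

    @pytest.mark.parametrize("name", sorted(pf.TEMPLATES))
    def test_every_template_profile_is_valid_hourglass(self, name):
        spec = pf.SyntheticSpec.from_template(name)
        prof = pf.make_area_profile(spec)
        assert prof.area_mm2.min() == pytest.approx(spec.amin_area_mm2)
        assert prof.landmarks["top"] < prof.landmarks["dividing"] < prof.landmarks["bottom"]
        i = int(np.argmin(prof.area_mm2))
        assert np.all(np.diff(prof.area_mm2[: i + 1]) < 0)  # monotone taper above

    def test_plateau_keeps_areas_within_five_percent_of_minimum(self):
        spec = pf.SyntheticSpec(
            length_mm=60, amin_area_mm2=80, amin_relative_position=0.3,
            constriction_plateau_mm=10.0, expansion_area_mm2=240,
        )
        prof = pf.make_area_profile(spec)
        within = np.sum(prof.area_mm2 <= 1.05 * prof.area_mm2.min())
        assert within >= 20  # 10 mm plateau at 0.5 mm spacing

    def test_amin_location_moves_monotonically_with_relative_position(self):
        locs = []
        for rel in (0.2, 0.35, 0.5, 0.65, 0.8):
            spec = pf.SyntheticSpec(amin_relative_position=rel)
            locs.append(np.argmin(pf.make_area_profile(spec).area_mm2))
        assert all(a < b for a, b in zip(locs, locs[1:]))

    def test_rejects_bad_geometry(self):
        with pytest.raises(ValueError):
            pf.SyntheticSpec(amin_relative_position=0.0)
        with pytest.raises(ValueError):
            pf.SyntheticSpec(amin_area_mm2=300, expansion_area_mm2=200)
        with pytest.raises(ValueError, match="plateau"):
            pf.make_area_profile(
                pf.SyntheticSpec(
                    length_mm=50, amin_relative_position=0.5,
                    constriction_plateau_mm=40.0,
                )
            )


class TestSurfaceMesh:
    def test_cylinder_slices_match_analytic_area(self, cylinder):
        mesh, prof = cylinder
        secs = pf.slice_airway(mesh, prof.z_mm[0], prof.z_mm[-1], 0.5)
        areas = np.array([s.area_mm2 for s in secs])
        assert np.all(np.abs(areas - np.pi * 25) / (np.pi * 25) < 0.01)

    def test_elliptical_section_preserves_area(self):
        prof = pf.AreaProfile(
            z_mm=20 - 0.5 * np.arange(41), area_mm2=np.full(41, 100.0)
        )
        mesh = pf.make_surface_mesh(prof, cross_section_shape="ellipse", ellipse_aspect=2.0)
        secs = pf.slice_airway(mesh, 20.0, 0.0, 0.5)
        for s in secs:
            assert s.area_mm2 == pytest.approx(100.0, rel=0.01)

    def test_template_mesh_recovers_configured_minimum(self, ftp4_spec, ftp4_mesh, ftp4_profile):
        secs = pf.slice_airway(ftp4_mesh, ftp4_profile.z_mm[0], ftp4_profile.z_mm[-1], 0.5)
        amin = min(secs, key=lambda s: s.area_mm2)
        assert amin.area_mm2 == pytest.approx(54.43, rel=0.02)

    def test_mesh_generation_is_seed_deterministic(self, ftp4_spec):
        prof1 = pf.make_area_profile(ftp4_spec)
        prof2 = pf.make_area_profile(ftp4_spec)
        m1 = pf.make_surface_mesh(prof1, ftp4_spec)
        m2 = pf.make_surface_mesh(prof2, ftp4_spec)
        assert np.array_equal(m1.vertices, m2.vertices)
        assert np.array_equal(m1.faces, m2.faces)


class TestPerturbMesh:
    def test_zero_amplitude_is_identity(self, cylinder):
        mesh, _ = cylinder
        out = pf.perturb_mesh(mesh, 0.0, seed=7)
        assert np.array_equal(out.vertices, mesh.vertices)

    def test_same_seed_reproduces(self, cylinder):
        mesh, _ = cylinder
        a = pf.perturb_mesh(mesh, 0.1, seed=11)
        b = pf.perturb_mesh(mesh, 0.1, seed=11)
        assert np.array_equal(a.vertices, b.vertices)

    def test_small_perturbation_keeps_slice_areas(self, cylinder):
        mesh, prof = cylinder
        out = pf.perturb_mesh(mesh, 0.1, seed=3)
        secs = pf.slice_airway(out, prof.z_mm[0] - 0.3, prof.z_mm[-1] + 0.3, 1.0)
        for s in secs:
            assert s.area_mm2 == pytest.approx(np.pi * 25, rel=0.05)

    def test_large_amplitude_warns(self, cylinder):
        mesh, _ = cylinder
        with pytest.warns(RuntimeWarning):
            pf.perturb_mesh(mesh, 2.0, seed=0)


class TestFlowField:
    def _flux_lpm(self, samples):
        out = {}
        for idx, grp in samples.planes.groupby("plane_index"):
            u = grp[["ux_ms", "uy_ms", "uz_ms"]].to_numpy()
            flux = (u @ samples.flow_direction * grp["area_weight_mm2"].to_numpy() * 1e-6).sum()
            out[idx] = flux * 60_000.0
        return out

    def test_uniform_forward_flow_when_beta_one(self, ftp4_profile):
        ff = pf.make_flow_field(ftp4_profile, 18.0, beta=1.0, seed=0)
        for _, grp in ff.planes.groupby("plane_index"):
            assert (grp["uz_ms"] < 0).all()  # all forward (downstream is -z)

    def test_reversed_area_fraction_matches_beta(self, ftp4_profile):
        ff = pf.make_flow_field(ftp4_profile, 18.0, beta=0.7, recirc_strength=0.2, seed=0)
        for _, grp in ff.planes.groupby("plane_index"):
            frac = pf.reverse_flow_fraction(
                grp[["ux_ms", "uy_ms", "uz_ms"]].to_numpy(),
                grp["area_weight_mm2"].to_numpy(),
                ff.flow_direction,
            )
            assert frac == pytest.approx(0.30, abs=0.02)

    @pytest.mark.parametrize("beta,gamma", [(1.0, 0.0), (0.7, 0.2), (0.5, 0.3)])
    def test_plane_flux_equals_flow_rate(self, ftp4_profile, beta, gamma):
        ff = pf.make_flow_field(ftp4_profile, 18.0, beta=beta, recirc_strength=gamma, seed=2)
        for flux in self._flux_lpm(ff).values():
            assert flux == pytest.approx(18.0, rel=0.01)

    def test_plane_area_weights_sum_to_plane_area(self, ftp4_profile):
        ff = pf.make_flow_field(ftp4_profile, 18.0, seed=0)
        for idx, grp in ff.planes.groupby("plane_index"):
            assert grp["area_weight_mm2"].sum() == pytest.approx(
                ftp4_profile.area_mm2[idx - 1], rel=0.005
            )

    def test_impossible_flux_normalization_is_explicit(self, ftp4_profile):
        with pytest.raises(FluxNormalizationError):
            pf.make_flow_field(ftp4_profile, 18.0, beta=0.3, recirc_strength=0.9)

    def test_seed_determinism(self, ftp4_profile):
        a = pf.make_flow_field(ftp4_profile, 18.0, seed=42)
        b = pf.make_flow_field(ftp4_profile, 18.0, seed=42)
        assert a.planes.equals(b.planes)
        assert a.wall.equals(b.wall)

    def test_tke_peaks_at_core_interface(self, ftp4_profile):
        ff = pf.make_flow_field(ftp4_profile, 18.0, beta=0.6, recirc_strength=0.2, seed=0)
        last = ff.planes[ff.planes.plane_index == ftp4_profile.n_planes]
        r = np.hypot(last["x_mm"], last["y_mm"]).to_numpy()
        r_core = np.sqrt(0.6 * ftp4_profile.area_mm2[-1] / np.pi)
        peak_r = r[np.argmax(last["tke_m2s2"].to_numpy())]
        assert abs(peak_r - r_core) < 0.3 * r.max()
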