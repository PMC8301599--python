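"""Closed-curve interpolation and 4D mesh construction."""

import numpy as np
import pytest

import echolv as e
from echolv.exceptions import GeometryError, InsufficientDataError
from echolv.phantom import radius_field, draw_animal_params


class TestInterpolateClosedCurve:
    def test_circle_is_reproduced_exactly(self):
        out = e.interpolate_closed_curve(np.full(6, 2.0))
        np.testing.assert_allclose(out, 2.0, atol=1e-9)

    @pytest.mark.parametrize("engine", ["spline", "hobby"])
    def test_interpolates_the_anchor_radii(self, engine):
        radii = np.array([1.2, 1.5, 1.3, 1.6, 1.25, 1.4])
        out = e.interpolate_closed_curve(
            radii, output_deg=np.asarray(e.ANCHOR_THETAS_DEG), engine=engine)
        np.testing.assert_allclose(out, radii, atol=1e-9)

    def test_hobby_engine_near_circular_on_circle(self):
        out = e.interpolate_closed_curve(np.full(6, 2.0), engine="hobby")
        np.testing.assert_allclose(out, 2.0, atol=5e-3)

    def test_arc_length_converges_under_refinement(self):
        """Ellipse-like pattern: coarse arc length within 2% of a 10x-dense one."""
        radii = 2.0 + 0.5 * np.cos(2 * np.radians(np.asarray(e.ANCHOR_THETAS_DEG)))

        def arc_length(n):
            deg = np.arange(n) * 360.0 / n
            r = e.interpolate_closed_curve(radii, output_deg=deg)
            th = np.radians(deg)
            xy = np.column_stack([r * np.cos(th), r * np.sin(th)])
            d = np.diff(np.vstack([xy, xy[:1]]), axis=0)
            return np.sum(np.hypot(d[:, 0], d[:, 1]))

        assert abs(arc_length(60) - arc_length(600)) / arc_length(600) < 0.02

    def test_non_positive_radius_rejected(self):
        with pytest.raises(GeometryError):
            e.interpolate_closed_curve([1.0, 1.0, -0.5, 1.0, 1.0, 1.0])


class TestBuildLVMesh:
    def test_standard_dimensions(self, truth_mesh):
        assert truth_mesh.radii.shape == (2, 60, 60, 60)
        assert len(truth_mesh.theta_deg) == 60
        assert len(truth_mesh.z_fracs) == 60
        assert len(truth_mesh.phases) == 60

    def test_time_constant_input_gives_identical_time_samples(self):
        F = 16
        phases = np.arange(F) / F
        values = np.tile(np.linspace(1.0, 3.0, 48), (F, 1))
        values = e.AnchorRadii(values=np.sort(values, axis=1), cycle_phase=phases,
                               validate=False)
        mesh = e.build_lv_mesh(values, np.zeros(F), np.full(F, 5.0))
        for t in range(1, mesh.n_time):
            np.testing.assert_allclose(mesh.radii[:, t], mesh.radii[:, 0], atol=1e-9)

    def test_mesh_reproduces_anchor_radii(self, small_dataset, small_truth):
        """Interpolation (not approximation): anchor values are hit exactly.

        Frame phases (k/16) lie on the 60-sample output grid only for some k,
        so evaluate the mesh at the input phases directly.
        """
        mesh = e.build_lv_mesh(small_truth, small_dataset.apex_z,
                               small_dataset.base_z,
                               phases_out=small_truth.cycle_phase)
        theta_idx = {th: i for i, th in enumerate(mesh.theta_deg)}
        z_idx = {round(z, 6): i for i, z in enumerate(np.round(mesh.z_fracs, 6))}
        for j, a in enumerate(e.anchor_grid()):
            b = 0 if a.boundary == "endo" else 1
            got = mesh.radii[b, :, z_idx[round(a.z_frac, 6)], theta_idx[a.theta_deg]]
            np.testing.assert_allclose(got, small_truth.values[:, j], atol=1e-6)

    def test_off_anchor_values_close_to_analytic_field(self, small_config):
        """Mesh values between anchors stay within 5% of the generating field."""
        params = draw_animal_params(small_config)[0]
        cfg = small_config
        F = cfg.frames_per_cycle
        phases = np.arange(F) / F
        truth = np.empty((F, 48))
        for j, a in enumerate(e.anchor_grid()):
            truth[:, j] = radius_field(params, cfg, a.theta_deg, a.z_frac, phases,
                                       a.boundary)
        radii = e.AnchorRadii(values=truth, cycle_phase=phases)
        mesh = e.build_lv_mesh(radii, np.zeros(F), np.full(F, cfg.lv_length_mm))
        # probe off-anchor samples away from the apex (the forced apex taper
        # deviates from the analytic profile at very low z by design)
        for it, iz, ith in [(7, 30, 10), (22, 45, 37), (41, 52, 21)]:
            analytic = radius_field(params, cfg, mesh.theta_deg[ith],
                                    mesh.z_fracs[iz], mesh.phases[it], "endo")
            got = mesh.radii[0, it, iz, ith]
            assert abs(got - analytic) / analytic < 0.05

    def test_temporal_periodicity(self, small_dataset, small_truth):
        mesh0 = e.build_lv_mesh(small_truth, small_dataset.apex_z,
                                small_dataset.base_z, phases_out=np.array([0.0]))
        mesh1 = e.build_lv_mesh(small_truth, small_dataset.apex_z,
                                small_dataset.base_z,
                                phases_out=np.array([1.0 - 1e-9]))
        np.testing.assert_allclose(mesh0.radii, mesh1.radii, atol=1e-6)

    def test_perimeter_converges_when_resolution_doubles(self, small_dataset,
                                                         small_truth):
        m60 = e.build_lv_mesh(small_truth, small_dataset.apex_z, small_dataset.base_z)
        m120 = e.build_lv_mesh(small_truth, small_dataset.apex_z,
                               small_dataset.base_z, n_theta=120, n_z=120)

        def perimeter(mesh, iz_frac):
            iz = int(round(iz_frac * len(mesh.z_fracs))) - 1
            r = mesh.radii[0, 0, iz]
            th = np.radians(mesh.theta_deg)
            xy = np.column_stack([r * np.cos(th), r * np.sin(th)])
            d = np.diff(np.vstack([xy, xy[:1]]), axis=0)
            return np.sum(np.hypot(d[:, 0], d[:, 1]))

        for frac in (0.5, 1.0):
            p1, p2 = perimeter(m60, frac), perimeter(m120, frac)
            assert abs(p1 - p2) / p2 < 0.005

    def test_too_few_frames_rejected(self):
        phases = np.arange(4) / 4
        radii = e.AnchorRadii(values=np.full((4, 48), 2.0), cycle_phase=phases)
        with pytest.raises(InsufficientDataError):
            e.build_lv_mesh(radii, np.zeros(4), np.full(4, 5.0))

    def test_hobby_engine_builds_equivalent_mesh(self, small_dataset, small_truth):
        ms = e.build_lv_mesh(small_truth, small_dataset.apex_z, small_dataset.base_z)
        mh = e.build_lv_mesh(small_truth, small_dataset.apex_z, small_dataset.base_z,
                             engine="hobby")
        # the two curve engines agree closely on smooth anatomical contours
        assert np.max(np.abs(ms.radii - mh.radii) / ms.radii) < 0.02


class TestExports:
    def test_obj_and_frame_roundtrip(self, truth_mesh, tmp_path):
        from echolv.mesh import mesh_to_frame

        path = tmp_path / "m.obj"
        e.mesh_to_obj(truth_mesh, "endo", 0, path)
        text = path.read_text().splitlines()
        n_vertices = sum(1 for line in text if line.startswith("v "))
        assert n_vertices == 60 * 60
        df = mesh_to_frame(truth_mesh)
        assert len(df) == 2 * 60 * 60 * 60
        np.testing.assert_allclose(
            np.hypot(df["x_mm"], df["y_mm"]), df["radius_mm"], atol=1e-9)
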