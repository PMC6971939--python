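"""Flow curves, peak systole, wall meshing and wall shear stress."""

import numpy as np
import pytest

import spiralflow as sf
from spiralflow.hemodynamics import BLOOD_VISCOSITY_PA_S, WallMesh


def series_from(data, frame_duration=100.0, voxel=0.8, discard=None):
    return sf.VelocitySeries(
        data=np.asarray(data, dtype=float),
        magnitude=np.ones(np.asarray(data).shape[1:]),
        venc=150.0,
        frame_duration_ms=frame_duration,
        voxel_size=voxel,
        discard_flags=(np.zeros(0, bool) if discard is None
                       else np.asarray(discard, bool)),
    )


class TestFlowRate:
    def test_uniform_velocity_times_area(self):
        # 10 cm/s over 1 cm^2 (100 pixels of 1 mm^2) -> 10 ml/s
        data = np.zeros((3, 1, 2, 10, 10))
        data[0, :, :, :, :] = 10.0
        vel = series_from(data)
        roi = sf.ROIPlane(axis=0, index=0, mask=np.ones((10, 10), bool),
                          pixel_area_mm2=1.0)
        curve = sf.flow_rate(vel, roi)
        np.testing.assert_allclose(curve.q, 10.0)

    def test_zero_field_gives_zero_curve(self):
        vel = series_from(np.zeros((3, 4, 2, 8, 8)))
        roi = sf.ROIPlane(axis=0, index=1, mask=np.ones((8, 8), bool),
                          pixel_area_mm2=0.64)
        np.testing.assert_array_equal(sf.flow_rate(vel, roi).q, 0.0)

    def test_parabolic_field_recovers_waveform(self, small_geometry,
                                               pulsatile_waveform):
        times = np.array([50.0, 150.0, 400.0])
        data = np.stack(
            [sf.velocity_field(small_geometry, pulsatile_waveform, t) for t in times],
            axis=1,
        )
        vel = series_from(data, voxel=small_geometry.voxel_size)
        lumen = small_geometry.lumen_mask()
        roi = sf.ROIPlane(axis=0, index=2, mask=lumen[2],
                          pixel_area_mm2=small_geometry.voxel_size**2)
        curve = sf.flow_rate(vel, roi)
        expected = sf.inlet_waveform(times, pulsatile_waveform)
        np.testing.assert_allclose(curve.q, expected, rtol=0.02)

    def test_flow_conserved_between_parallel_planes(self, small_geometry,
                                                    steady_waveform):
        data = sf.velocity_field(small_geometry, steady_waveform, 0.0)[:, None]
        vel = series_from(data, voxel=small_geometry.voxel_size)
        lumen = small_geometry.lumen_mask()
        qs = []
        for idx in (0, 3):
            roi = sf.ROIPlane(axis=0, index=idx, mask=lumen[idx],
                              pixel_area_mm2=small_geometry.voxel_size**2)
            qs.append(sf.flow_rate(vel, roi).q[0])
        assert qs[0] == pytest.approx(qs[1], rel=0.03)

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError):
            sf.ROIPlane(axis=0, index=0, mask=np.zeros((4, 4), bool),
                        pixel_area_mm2=1.0)


class TestPeakSystole:
    def lumen(self):
        return np.ones((2, 3, 3), dtype=bool)

    def vel_with_speeds(self, speeds, discard=None):
        T = len(speeds)
        data = np.zeros((3, T, 2, 3, 3))
        for t, s in enumerate(speeds):
            data[0, t] = s
        return series_from(data, discard=discard)

    def test_argmax_of_mean_speed(self):
        assert sf.peak_systole_frame(self.vel_with_speeds([1, 3, 2]), self.lumen()) == 1

    def test_tie_resolves_to_earliest(self):
        assert sf.peak_systole_frame(self.vel_with_speeds([3, 3, 1]), self.lumen()) == 0

    def test_discarded_frames_excluded(self):
        vel = self.vel_with_speeds([1, 2, 9], discard=[False, False, True])
        assert sf.peak_systole_frame(vel, self.lumen()) == 1

    def test_matches_waveform_peak_on_phantom(self, small_geometry,
                                              pulsatile_waveform):
        # frame centres at 50, 150, ..., 950 ms; waveform peaks at 150 ms
        centres = np.arange(10) * 100.0 + 50.0
        data = np.stack(
            [sf.velocity_field(small_geometry, pulsatile_waveform, t) for t in centres],
            axis=1,
        )
        vel = series_from(data)
        frame = sf.peak_systole_frame(vel, small_geometry.lumen_mask())
        assert frame == np.argmax(sf.inlet_waveform(centres, pulsatile_waveform))


class TestWallMesh:
    def cylinder_mask(self, radius=5.0, voxel=0.8, n=32, nx=6):
        geom = sf.VesselGeometry(grid_shape=(nx, n, n), radius_mm=radius,
                                 voxel_size=voxel)
        return geom, geom.lumen_mask()

    def test_wall_points_at_cylinder_radius(self):
        geom, mask = self.cylinder_mask()
        mesh = sf.wall_mesh(mask, geom.voxel_size)
        centre = (np.array(mask.shape) - 1) / 2.0 * geom.voxel_size
        d = np.hypot(mesh.points[:, 1] - centre[1], mesh.points[:, 2] - centre[2])
        assert np.all(np.abs(d - 5.0) <= geom.voxel_size)

    def test_normals_perpendicular_to_axis(self):
        geom, mask = self.cylinder_mask()
        mesh = sf.wall_mesh(mask, geom.voxel_size)
        # ignore points near the open tube ends where the surface is cut
        interior = (mesh.points[:, 0] > geom.voxel_size) & (
            mesh.points[:, 0] < (mask.shape[0] - 2) * geom.voxel_size
        )
        axial = np.abs(mesh.normals[interior, 0])
        assert np.all(axial <= np.sin(np.deg2rad(5.0)))

    def test_normals_unit_and_inward(self):
        geom, mask = self.cylinder_mask()
        mesh = sf.wall_mesh(mask, geom.voxel_size)
        np.testing.assert_allclose(np.linalg.norm(mesh.normals, axis=1), 1.0,
                                   atol=1e-9)
        centre = (np.array(mask.shape) - 1) / 2.0 * geom.voxel_size
        to_axis = np.zeros_like(mesh.points)
        to_axis[:, 1] = centre[1] - mesh.points[:, 1]
        to_axis[:, 2] = centre[2] - mesh.points[:, 2]
        dots = np.einsum("ij,ij->i", mesh.normals, to_axis)
        assert (dots > 0).mean() > 0.95

    def test_degenerate_masks_rejected(self):
        with pytest.raises(ValueError):
            sf.wall_mesh(np.zeros((4, 4, 4), bool), 1.0)
        with pytest.raises(ValueError):
            sf.wall_mesh(np.ones((4, 4, 4), bool), 1.0)


class TestWSS:
    def test_linear_shear_recovers_eta_gamma(self):
        """v_x' = gamma * z' with gamma = 100/s gives |tau| = 0.32 Pa."""
        gamma = 100.0  # 1/s
        voxel = 0.8
        n = 16
        z = (np.arange(n) - (n - 1) / 2) * voxel  # mm
        vx = gamma * np.clip(z, 0, None) * 1e-3 * 100.0  # cm/s, zero below wall
        velocity = np.zeros((3, 4, 4, n))
        velocity[0] = vx[None, None, :]
        # wall plane sits at z = 0, i.e. grid position (n-1)/2 * voxel
        mesh = WallMesh(
            points=np.array([[1.5 * voxel, 1.5 * voxel, (n - 1) / 2 * voxel]]),
            normals=np.array([[0.0, 0.0, 1.0]]),
            voxel_size=voxel,
        )
        field = sf.wss(velocity, mesh, eta=BLOOD_VISCOSITY_PA_S)
        assert field.magnitude[0] == pytest.approx(0.32, rel=1e-6)

    def test_zero_velocity_gives_zero_wss(self):
        mesh = WallMesh(points=np.array([[2.0, 2.0, 2.0]]),
                        normals=np.array([[1.0, 0.0, 0.0]]), voxel_size=1.0)
        field = sf.wss(np.zeros((3, 8, 8, 8)), mesh)
        np.testing.assert_allclose(field.tau, 0.0, atol=1e-15)

    def test_poiseuille_wall_shear(self, steady_waveform):
        """|tau| ~= 4 eta Q / (pi a^3) within 15% at 0.8 mm resolution."""
        geom = sf.VesselGeometry(grid_shape=(6, 33, 33), radius_mm=3.0,
                                 voxel_size=0.8)
        velocity = sf.velocity_field(geom, steady_waveform, 0.0)
        mesh = sf.wall_mesh(geom.lumen_mask(), geom.voxel_size)
        interior = (mesh.points[:, 0] > geom.voxel_size) & (
            mesh.points[:, 0] < (geom.grid_shape[0] - 2) * geom.voxel_size
        )
        field = sf.wss(velocity, mesh)
        analytic = 4 * BLOOD_VISCOSITY_PA_S * 3.0 / (np.pi * 0.3**3)  # Pa
        mean_tau = np.nanmean(field.magnitude[interior & field.valid])
        assert mean_tau == pytest.approx(analytic, rel=0.15)

    def test_tau_orthogonal_to_normal(self, steady_waveform):
        geom = sf.VesselGeometry(grid_shape=(4, 33, 33), radius_mm=3.0,
                                 voxel_size=0.8)
        velocity = sf.velocity_field(geom, steady_waveform, 0.0)
        mesh = sf.wall_mesh(geom.lumen_mask(), geom.voxel_size)
        field = sf.wss(velocity, mesh)
        ok = field.valid
        dots = np.einsum("ij,ij->i", field.tau[ok], field.normals[ok])
        mags = field.magnitude[ok]
        assert np.all(np.abs(dots) <= 1e-6 * np.maximum(mags, 1e-12))

    def test_linear_in_viscosity_and_velocity(self, steady_waveform):
        geom = sf.VesselGeometry(grid_shape=(4, 33, 33), radius_mm=3.0,
                                 voxel_size=0.8)
        velocity = sf.velocity_field(geom, steady_waveform, 0.0)
        mesh = sf.wall_mesh(geom.lumen_mask(), geom.voxel_size)
        base = sf.wss(velocity, mesh, eta=BLOOD_VISCOSITY_PA_S)
        double_eta = sf.wss(velocity, mesh, eta=2 * BLOOD_VISCOSITY_PA_S)
        double_vel = sf.wss(2 * velocity, mesh, eta=BLOOD_VISCOSITY_PA_S)
        np.testing.assert_allclose(double_eta.tau, 2 * base.tau, atol=1e-12)
        np.testing.assert_allclose(double_vel.tau, 2 * base.tau, atol=1e-12)

    def test_ray_exiting_grid_flagged(self):
        mesh = WallMesh(points=np.array([[0.5, 0.5, 0.5]]),
                        normals=np.array([[-1.0, 0.0, 0.0]]), voxel_size=1.0)
        field = sf.wss(np.zeros((3, 4, 4, 4)), mesh)
        assert not field.valid[0]
        assert np.isnan(field.tau[0]).all()


class TestResampling:
    def make_field(self, points, values):
        n = len(points)
        tau = np.zeros((n, 3))
        tau[:, 0] = values
        return sf.WSSField(
            points=np.asarray(points, float),
            normals=np.tile([[1.0, 0, 0]], (n, 1)),
            tau=tau, eta=BLOOD_VISCOSITY_PA_S,
            valid=np.ones(n, bool), voxel_size=1.0,
        )

    def test_identical_meshes_identity_pairing(self):
        pts = np.random.default_rng(0).random((20, 3)) * 10
        a = self.make_field(pts, np.arange(20.0))
        ref_v, test_v, dropped = sf.resample_wss_to_reference(a, a)
        np.testing.assert_array_equal(ref_v, test_v)
        assert dropped == 0

    def test_small_translation_keeps_pairs(self):
        pts = np.random.default_rng(1).random((200, 3)) * 20
        a = self.make_field(pts, np.arange(200.0))
        b = self.make_field(pts + 0.1, np.arange(200.0))
        ref_v, test_v, dropped = sf.resample_wss_to_reference(a, b)
        assert len(ref_v) >= 0.99 * 200
        assert (ref_v == test_v).mean() >= 0.99

    def test_disjoint_geometries_raise(self):
        a = self.make_field(np.zeros((5, 3)), np.ones(5))
        b = self.make_field(np.full((5, 3), 100.0), np.ones(5))
        with pytest.raises(ValueError, match="exceeded"):
            sf.resample_wss_to_reference(a, b)

    def test_velocity_pairing_matches_masks(self):
        rng = np.random.default_rng(2)
        ref = series_from(rng.standard_normal((3, 2, 4, 6, 6)))
        test = series_from(rng.standard_normal((3, 2, 4, 6, 6)))
        lumen = rng.random((4, 6, 6)) > 0.5
        a, b = sf.resample_velocity_to_reference(ref, test, lumen, 0, 1)
        assert len(a) == len(b) == lumen.sum()


class TestStrokeVolume:
    def test_constant_flow_rectangle_rule(self):
        curve = sf.FlowCurve(q=np.full(10, 3.0), frame_duration_ms=100.0)
        assert sf.stroke_volume(curve) == pytest.approx(3.0)

    def test_zero_curve(self):
        curve = sf.FlowCurve(q=np.zeros(5), frame_duration_ms=200.0)
        assert sf.stroke_volume(curve) == 0.0

    def test_phantom_waveform_integral(self, pulsatile_waveform):
        centres = np.arange(20) * 50.0 + 25.0
        q = sf.inlet_waveform(centres, pulsatile_waveform)
        curve = sf.FlowCurve(q=q, frame_duration_ms=50.0)
        # full cycle: mean 3 ml/s for 1 s -> 3 ml
        assert sf.stroke_volume(curve) == pytest.approx(3.0, rel=0.03)

    def test_discarded_frames_excluded(self):
        flags = np.zeros(10, bool)
        flags[-2:] = True
        curve = sf.FlowCurve(q=np.full(10, 3.0), frame_duration_ms=100.0,
                             discard_flags=flags)
        assert sf.stroke_volume(curve) == pytest.approx(2.4)


def test_wss_table_export(tmp_path, steady_waveform):
    geom = sf.VesselGeometry(grid_shape=(4, 33, 33), radius_mm=3.0, voxel_size=0.8)
    velocity = sf.velocity_field(geom, steady_waveform, 0.0)
    mesh = sf.wall_mesh(geom.lumen_mask(), geom.voxel_size)
    field = sf.wss(velocity, mesh)
    path = str(tmp_path / "wss.tsv")
    sf.save_wss_table(field, path)
    table = np.loadtxt(path)
    assert table.shape == (int(field.valid.sum()), 10)
    np.testing.assert_allclose(table[:, 9], field.magnitude[field.valid],
                               rtol=1e-4)
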