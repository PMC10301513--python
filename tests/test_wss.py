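"""Surface extraction, near-wall sampling and parabolic wall shear stress."""

import numpy as np
import pytest

import aortaflow as af
from aortaflow.wss import max_wss_absdiff


class TestExtractSurface:
    def test_sphere_area_within_five_percent(self, sphere_mask):
        mask = sphere_mask(radius_mm=10.0, n=40, spacing=1.0)
        mesh = af.extract_surface(mask)
        assert mesh.area() == pytest.approx(4 * np.pi * 100.0, rel=0.05)

    def test_sphere_normals_point_outward(self, sphere_mask):
        mask = sphere_mask(radius_mm=10.0, n=40, spacing=1.0)
        mesh = af.extract_surface(mask)
        center = (np.array(mask.voxels.shape) - 1) * mask.spacing / 2.0
        radial = mesh.vertices - center
        radial /= np.linalg.norm(radial, axis=1, keepdims=True)
        outward = np.sum(radial * mesh.normals, axis=1) > 0
        assert outward.mean() >= 0.99

    def test_single_voxel_mask_gives_closed_mesh(self):
        vox = np.zeros((10, 10, 10), bool)
        vox[5, 5, 5] = True
        mesh = af.extract_surface(af.SegmentationMask(vox, np.ones(3)))
        assert mesh.n_vertices > 0 and mesh.faces.shape[0] > 0

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            af.extract_surface(af.SegmentationMask(np.zeros((5, 5, 5), bool), np.ones(3)))


class TestSampleWallProfile:
    def _flat_wall_mesh(self, normal):
        verts = np.array([[10.0, 10.0, 10.0], [12.0, 10.0, 10.0]])
        faces = np.zeros((0, 3), dtype=np.int64)
        normals = np.tile(np.asarray(normal, float), (2, 1))
        return af.SurfaceMesh(verts, faces, normals)

    def test_flow_along_normal_has_zero_tangential_speed(self):
        v = np.zeros((20, 20, 20, 3))
        v[..., 2] = 10.0  # uniform flow along z
        mesh = self._flat_wall_mesh([0.0, 0.0, 1.0])
        vt1, vt2, valid, _ = af.sample_wall_profile(mesh, v, np.ones(3))
        assert np.all(valid)
        np.testing.assert_allclose(vt1, 0.0, atol=1e-9)
        np.testing.assert_allclose(vt2, 0.0, atol=1e-9)

    def test_flow_perpendicular_to_normal_passes_through(self):
        v = np.zeros((20, 20, 20, 3))
        v[..., 0] = 10.0  # uniform v=(10,0,0), wall normal (0,0,1)
        mesh = self._flat_wall_mesh([0.0, 0.0, 1.0])
        vt1, vt2, _, _ = af.sample_wall_profile(mesh, v, np.ones(3))
        np.testing.assert_allclose(vt1, 10.0)
        np.testing.assert_allclose(vt2, 10.0)

    def test_poiseuille_profile_is_monotone(self, phantom_default):
        cfg, ds, truth = phantom_default
        mesh = af.extract_surface(truth.lumen_mask)
        vt1, vt2, valid, _ = af.sample_wall_profile(
            mesh, ds.velocity[..., cfg.systolic_frame, :], ds.spacing
        )
        assert np.all(vt1[valid] < vt2[valid])

    def test_out_of_volume_samples_flagged(self):
        mesh = af.SurfaceMesh(
            np.array([[0.5, 0.5, 0.5]]),
            np.zeros((0, 3), dtype=np.int64),
            np.array([[0.0, 0.0, 1.0]]),  # inward direction (-n) exits the grid
        )
        v = np.zeros((10, 10, 10, 3))
        _, _, valid, _ = af.sample_wall_profile(mesh, v, np.ones(3))
        assert not valid[0]


class TestParabolicFit:
    def test_zero_samples_give_zero_stress(self):
        assert af.wss_parabolic(0.0, 0.0, 2.0) == 0.0

    def test_hand_computed_reference(self):
        # h=2 mm, v1=10 cm/s, v2=16 cm/s, mu=3.2e-3: grad 60 1/s -> 0.192 Pa
        assert af.wss_parabolic(10.0, 16.0, 2.0) == pytest.approx(0.192)

    def test_exact_for_linear_profile(self):
        # v(y) = 2 cm/s per mm: gradient 2 recovered exactly
        h = 1.7
        tau = af.wss_parabolic(2 * h, 2 * 2 * h, h, mu=1.0)
        grad_si = tau / 1.0
        assert grad_si == pytest.approx(2.0 * 0.01 / 1e-3)

    def test_linear_in_mu_and_velocity(self):
        base = af.wss_parabolic(10.0, 16.0, 2.0, mu=3.2e-3)
        assert af.wss_parabolic(10.0, 16.0, 2.0, mu=6.4e-3) == pytest.approx(2 * base)
        assert af.wss_parabolic(20.0, 32.0, 2.0, mu=3.2e-3) == pytest.approx(2 * base)

    def test_nonpositive_depth_rejected(self):
        with pytest.raises(ValueError):
            af.wss_parabolic(1.0, 2.0, 0.0)


class TestPhantomWSS:
    def test_median_wss_within_15_percent_and_converging(self, phantom_default):
        cfg, ds, truth = phantom_default
        analytic = truth.max_wss_at_systole()
        _, res = af.compute_wss(truth.lumen_mask, ds.velocity[..., cfg.systolic_frame, :])
        err_coarse = abs(np.median(res.tau_w[res.valid]) - analytic) / analytic
        assert err_coarse < 0.15

        fine_cfg = af.PhantomConfig(grid_shape=(128, 128, 128), spacing=(1.0, 1.0, 1.0))
        ds_f, truth_f = af.make_tube_phantom(fine_cfg)
        _, res_f = af.compute_wss(truth_f.lumen_mask, ds_f.velocity[..., 8, :])
        err_fine = abs(np.median(res_f.tau_w[res_f.valid]) - analytic) / analytic
        assert err_fine < err_coarse

    def test_global_max_within_15_percent(self, phantom_default):
        cfg, ds, truth = phantom_default
        mesh, res = af.compute_wss(truth.lumen_mask, ds.velocity[..., cfg.systolic_frame, :])
        summary = af.regional_max_wss(res, mesh, truth.region_labels, ds.spacing)
        assert summary["whole"] == pytest.approx(truth.max_wss_at_systole(), rel=0.15)

    def test_wss_scales_with_velocity_amplitude(self, phantom_default):
        cfg, ds, truth = phantom_default
        frame = cfg.systolic_frame
        _, res1 = af.compute_wss(truth.lumen_mask, ds.velocity[..., frame, :])
        _, res2 = af.compute_wss(truth.lumen_mask, 2.0 * ds.velocity[..., frame, :])
        v = res1.valid
        np.testing.assert_allclose(res2.tau_w[v], 2.0 * res1.tau_w[v], rtol=1e-9)


class TestRegionalMax:
    def test_constant_stress_everywhere(self, phantom_ubend):
        _, _, truth = phantom_ubend
        mesh = af.extract_surface(truth.lumen_mask)
        res = af.WSSResult(
            np.full(mesh.n_vertices, 1.5), 3.2e-3, 2.0, np.ones(mesh.n_vertices, bool)
        )
        summary = af.regional_max_wss(res, mesh, truth.region_labels, truth.lumen_mask.spacing)
        for key, value in summary.items():
            assert value == pytest.approx(1.5)
        assert len(summary) == 4  # whole + three regions

    def test_identical_inputs_give_zero_absdiff(self, phantom_default):
        cfg, ds, truth = phantom_default
        mesh, res = af.compute_wss(truth.lumen_mask, ds.velocity[..., cfg.systolic_frame, :])
        a = af.regional_max_wss(res, mesh, truth.region_labels, ds.spacing)
        diff = max_wss_absdiff(a, a)
        assert all(v == 0.0 for v in diff.values())
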