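"""Phase-offset correction: candidate/stationary selection, OLS fit, subtraction."""

import numpy as np
import pytest

import aortaflow as af


def _dataset(mag3d, vel=None, n_frames=3):
    """Wrap a 3D magnitude (and optional velocity) into a FlowDataset."""
    shape = mag3d.shape
    mag = np.repeat(mag3d[..., None], n_frames, axis=3)
    if vel is None:
        vel = np.zeros(shape + (n_frames, 3))
    return af.FlowDataset(mag, vel, np.ones(3), np.arange(n_frames, dtype=float), 200.0)


class TestCandidateMask:
    def test_percentile_15_of_1_to_100(self):
        # linear-interpolated 15th percentile of 1..100 is 15.85 -> 16..100 kept
        mag = np.arange(1.0, 101.0).reshape(10, 10, 1)
        mask = af.magnitude_candidate_mask(_dataset(mag), 15.0)
        assert mask.n_voxels == 85
        assert not mask.voxels.reshape(100)[:15].any()

    def test_percentile_zero_keeps_all(self):
        mag = np.arange(1.0, 28.0).reshape(3, 3, 3)
        assert af.magnitude_candidate_mask(_dataset(mag), 0.0).n_voxels == 27

    def test_constant_magnitude_keeps_all(self):
        mag = np.full((4, 4, 4), 7.0)
        assert af.magnitude_candidate_mask(_dataset(mag), 15.0).n_voxels == 64

    def test_invalid_percentile_rejected(self):
        with pytest.raises(ValueError):
            af.magnitude_candidate_mask(_dataset(np.ones((3, 3, 3))), 120.0)


class TestStationaryMask:
    def test_bimodal_sd_selects_zero_sd_half(self):
        shape = (10, 10, 1)
        vel = np.zeros(shape + (4, 3))
        pulsatile = np.zeros(shape, dtype=bool)
        pulsatile[5:] = True  # half the voxels oscillate: population s.d. 10
        vel[pulsatile, :, 0] = np.array([-10.0, 10.0, -10.0, 10.0])
        ds = _dataset(np.ones(shape), vel, n_frames=4)
        cand = af.SegmentationMask(np.ones(shape, bool), np.ones(3))
        sel = af.stationary_tissue_mask(ds, cand, "x")
        np.testing.assert_array_equal(sel.voxels, ~pulsatile)

    def test_constant_velocity_triggers_fallback_to_all(self, caplog):
        ds = _dataset(np.ones((4, 4, 4)))  # zero velocity everywhere
        cand = af.SegmentationMask(np.ones((4, 4, 4), bool), np.ones(3))
        with caplog.at_level("INFO"):
            sel = af.stationary_tissue_mask(ds, cand, "x")
        assert sel.n_voxels == 64  # all-equal s.d.: fallback keeps all candidates
        assert any("fallback" in r.message.lower() or "degenerate" in r.message.lower()
                   for r in caplog.records)

    def test_phantom_selection_subset_of_background(self, phantom_default):
        _, ds, truth = phantom_default
        cand = af.magnitude_candidate_mask(ds, 15.0)
        sel = af.stationary_tissue_mask(ds, cand, "z")
        assert not (sel.voxels & truth.lumen_mask.voxels).any()

    def test_empty_candidates_rejected(self, phantom_small):
        _, ds, _ = phantom_small
        empty = af.SegmentationMask(np.zeros(ds.spatial_shape, bool), ds.spacing)
        with pytest.raises(ValueError):
            af.stationary_tissue_mask(ds, empty, "x")


class TestOffsetFit:
    def test_zero_velocity_gives_zero_coefficients(self):
        ds = _dataset(np.ones((8, 8, 8)))
        stationary = af.SegmentationMask(np.ones((8, 8, 8), bool), np.ones(3))
        model, offset = af.fit_offset_surface(ds, stationary, "x")
        np.testing.assert_allclose(model.coeffs, 0.0, atol=1e-9)
        np.testing.assert_allclose(offset, 0.0, atol=1e-9)

    def test_injected_cubic_recovered_exactly(self):
        rng = np.random.default_rng(42)
        coeffs = rng.normal(0, 3.0, (3, 20))
        cfg = af.PhantomConfig(offset_coeffs=coeffs)
        ds, _ = af.make_tube_phantom(cfg)
        _, model = af.correct_phase_offset(ds)
        rel = np.abs(model.coeffs - coeffs) / np.abs(coeffs)
        assert rel.max() < 1e-6

    def test_pure_constant_offset(self, phantom_small):
        _, ds, _ = phantom_small
        coeffs = np.zeros((3, 20))
        coeffs[2, 0] = 3.5
        shifted = af.apply_phase_offset(ds, coeffs)
        _, model = af.correct_phase_offset(shifted)
        assert model.coeffs[2, 0] == pytest.approx(3.5, abs=1e-9)
        np.testing.assert_allclose(model.coeffs[2, 1:], 0.0, atol=1e-9)

    def test_too_few_samples_rejected(self, phantom_small):
        _, ds, _ = phantom_small
        tiny = np.zeros(ds.spatial_shape, bool)
        tiny[0, 0, :10] = True
        with pytest.raises(ValueError, match="at least"):
            af.fit_offset_surface(ds, af.SegmentationMask(tiny, ds.spacing), "x")


class TestCorrection:
    def test_offset_free_phantom_unchanged(self, phantom_default):
        _, ds, _ = phantom_default
        corrected, _ = af.correct_phase_offset(ds)
        assert np.abs(corrected.velocity - ds.velocity).max() < 1e-6

    def test_injected_offset_removed_from_background(self):
        rng = np.random.default_rng(3)
        cfg = af.PhantomConfig(offset_coeffs=rng.normal(0, 2.0, (3, 20)))
        ds, truth = af.make_tube_phantom(cfg)
        corrected, _ = af.correct_phase_offset(ds)
        bg = ~truth.lumen_mask.voxels
        assert np.abs(corrected.velocity[bg]).max() < 1e-4

    def test_lumen_changes_only_by_local_offset(self, phantom_small):
        _, ds, truth = phantom_small
        rng = np.random.default_rng(5)
        coeffs = rng.normal(0, 1.0, (3, 20))
        shifted = af.apply_phase_offset(ds, coeffs)
        corrected, model = af.correct_phase_offset(shifted)
        # subtraction is local: corrected lumen equals the clean lumen
        lum = truth.lumen_mask.voxels
        np.testing.assert_allclose(
            corrected.velocity[lum], ds.velocity[lum], atol=1e-8
        )

    def test_correction_idempotent(self):
        rng = np.random.default_rng(9)
        cfg = af.PhantomConfig(offset_coeffs=rng.normal(0, 2.0, (3, 20)))
        ds, _ = af.make_tube_phantom(cfg)
        once, _ = af.correct_phase_offset(ds)
        twice, _ = af.correct_phase_offset(once)
        assert np.abs(twice.velocity - once.velocity).max() < 1e-3


class TestNormalizeMagnitude:
    def test_affine_map(self):
        mag = np.array([2.0, 6.0, 10.0] * 9).reshape(3, 3, 3)
        out = af.normalize_magnitude(_dataset(mag))
        vals = np.unique(out.magnitude)
        np.testing.assert_allclose(vals, [0.0, 0.5, 1.0])

    def test_idempotent_on_unit_range(self, phantom_small):
        _, ds, _ = phantom_small
        once = af.normalize_magnitude(ds)
        twice = af.normalize_magnitude(once)
        np.testing.assert_allclose(twice.magnitude, once.magnitude)
        assert once.magnitude.min() == 0.0 and once.magnitude.max() == 1.0

    def test_constant_magnitude_rejected(self):
        with pytest.raises(ValueError):
            af.normalize_magnitude(_dataset(np.full((3, 3, 3), 5.0)))

    def test_velocities_untouched(self, phantom_small):
        _, ds, _ = phantom_small
        out = af.normalize_magnitude(ds)
        np.testing.assert_array_equal(out.velocity, ds.velocity)
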