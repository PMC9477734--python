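"""Surface-manifold estimation and surface-restricted projections."""

import numpy as np
import pytest
from scipy.ndimage import shift as ndshift

import pavecell as pc
from pavecell.scene import _integrated_gaussian_patch


def _flat_stack(nz=30, ny=24, nx=24, z0=20, amp=100.0):
    z = np.arange(nz, dtype=float)[:, None, None]
    data = amp * np.exp(-0.5 * ((z - z0) / 0.8) ** 2)
    return pc.ImageStack(np.broadcast_to(data, (nz, ny, nx)).copy(), 110.0)


class TestEstimateManifold:
    def test_flat_noiseless_band_recovered_exactly(self):
        man = pc.estimate_manifold(_flat_stack())
        assert np.allclose(man.heights, 20.0, atol=1e-9)

    def test_sinusoid_rms_below_half_zstep(self, sinusoid_scene):
        _, ref, _, truth = sinusoid_scene
        man = pc.estimate_manifold(ref)
        rms = np.sqrt(np.mean((man.heights - truth.manifold) ** 2))
        assert rms < 0.5

    def test_deep_blob_outlier_rejected(self):
        stack = _flat_stack(nz=40, ny=40, nx=40, z0=10)
        data = stack.data.copy()
        # bright blob 12 slices below the surface, brighter than the band
        zz, yy, xx = np.mgrid[0:40, 0:40, 0:40].astype(float)
        data += 1000 * np.exp(
            -0.5 * (((zz - 22) / 2) ** 2 + ((yy - 20) / 2) ** 2 + ((xx - 20) / 2) ** 2)
        )
        man = pc.estimate_manifold(pc.ImageStack(data, 110.0))
        assert abs(man.heights[20, 20] - 10.0) <= 1.0

    def test_all_zero_stack_raises(self):
        with pytest.raises(ValueError, match="no surface signal"):
            pc.estimate_manifold(pc.ImageStack(np.zeros((5, 8, 8)), 110.0))

    def test_lateral_translation_equivariance(self, sinusoid_scene):
        _, ref, _, _ = sinusoid_scene
        man = pc.estimate_manifold(ref)
        rolled = pc.ImageStack(np.roll(ref.data, 7, axis=2), ref.pixel_size_nm)
        man2 = pc.estimate_manifold(rolled)
        # compare away from image borders and the circular wrap seam (x ~ 0-7)
        core = np.s_[40:-40, 60:-40]
        assert np.allclose(np.roll(man.heights, 7, axis=1)[core], man2.heights[core], atol=1e-6)


class TestProjection:
    def test_integer_manifold_selects_slice_exactly(self):
        rng = np.random.default_rng(0)
        data = rng.uniform(0, 100, (10, 16, 16))
        stack = pc.ImageStack(data, 110.0)
        man = pc.SurfaceManifold(np.full((16, 16), 4.0), n_z=10)
        proj = pc.project_at_surface(stack, man)
        assert np.array_equal(proj.image, data[4])

    def test_half_integer_manifold_interpolates_linearly(self):
        z = np.arange(8, dtype=float)
        data = np.broadcast_to(z[:, None, None] * 10, (8, 4, 4)).copy()
        stack = pc.ImageStack(data, 110.0)
        man = pc.SurfaceManifold(np.full((4, 4), 3.5), n_z=8)
        proj = pc.project_at_surface(stack, man)
        assert np.allclose(proj.image, 35.0)

    def test_surface_value_read_not_deep_blob(self):
        data = np.zeros((20, 8, 8))
        data[5] = 100.0
        data[15] = 1000.0
        stack = pc.ImageStack(data, 110.0)
        man = pc.SurfaceManifold(np.full((8, 8), 5.0), n_z=20)
        assert np.allclose(pc.project_at_surface(stack, man).image, 100.0)

    def test_same_manifold_reusable_across_channels(self, sinusoid_scene):
        _, ref, tgt, _ = sinusoid_scene
        man = pc.estimate_manifold(ref)
        p_ref = pc.project_at_surface(ref, man)
        p_tgt = pc.project_at_surface(tgt, man)
        assert p_ref.image.shape == p_tgt.image.shape
        # the surface is the brightest structure in the reference channel
        col_mean = ref.data.mean(axis=0)
        assert (p_ref.image >= col_mean).mean() > 0.99

    def test_mip_depth_nz_equals_whole_stack_mip(self):
        rng = np.random.default_rng(1)
        data = rng.uniform(0, 50, (12, 10, 10))
        stack = pc.ImageStack(data, 110.0)
        man = pc.SurfaceManifold(np.zeros((10, 10)), n_z=12)
        proj = pc.project_surface_mip(stack, man, depth=12)
        assert np.array_equal(proj.image, data.max(axis=0))

    def test_deep_blob_attenuated_in_depth3_mip(self, sinusoid_scene):
        _, ref, tgt, truth = sinusoid_scene
        man = pc.estimate_manifold(ref)
        mip3 = pc.project_surface_mip(tgt, man, depth=3).image
        whole = tgt.data.max(axis=0)
        by = truth.blob_centers[:, 1].round().astype(int)
        bx = truth.blob_centers[:, 2].round().astype(int)
        attenuation = mip3[by, bx] / whole[by, bx]
        assert attenuation.mean() <= 0.10

    def test_surface_puncta_retained_in_depth3_mip(self, sinusoid_scene):
        _, ref, tgt, truth = sinusoid_scene
        man = pc.estimate_manifold(ref)
        mip3 = pc.project_surface_mip(tgt, man, depth=3).image
        whole = tgt.data.max(axis=0)
        py = truth.puncta[:, 1].round().astype(int)
        px = truth.puncta[:, 0].round().astype(int)
        retained = mip3[py, px] / whole[py, px]
        assert (retained >= 0.5).mean() >= 0.95

    def test_shape_mismatch_raises(self):
        stack = _flat_stack()
        man = pc.SurfaceManifold(np.zeros((4, 4)), n_z=30)
        with pytest.raises(ValueError):
            pc.project_at_surface(stack, man)


class TestRollingBall:
    def test_constant_image_maps_to_zero(self):
        out = pc.rolling_ball_subtract(np.full((32, 32), 42.0), 10)
        assert np.allclose(out, 0.0, atol=1e-6)

    def test_spot_on_ramp_intensity_preserved(self):
        yy, xx = np.mgrid[0:64, 0:64].astype(float)
        ramp = 0.5 * xx + 0.3 * yy + 20
        spot = _integrated_gaussian_patch(32.0, 30.0, 1.6, 1000.0, (64, 64))
        sub = pc.rolling_ball_subtract(ramp + spot, 15)
        # integrated intensity via the Gaussian fitter (background-free)
        recs = pc.fit_spots(sub, np.array([[32, 30]]))
        assert len(recs) == 1
        assert recs[0].intensity == pytest.approx(1000.0, rel=0.10)

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError):
            pc.rolling_ball_subtract(np.zeros((8, 8)), 0)


class TestRegistration:
    @staticmethod
    def _scene():
        rng = np.random.default_rng(4)
        base = rng.normal(20, 2, (64, 64))
        base += _integrated_gaussian_patch(30, 28, 3.0, 5000, (64, 64))
        base += _integrated_gaussian_patch(45, 50, 2.0, 3000, (64, 64))
        return base

    def test_integer_drift_recovered(self):
        base = self._scene()
        drifted = ndshift(base, (3, -2), order=1, mode="nearest")
        stack = pc.ImageStack(np.stack([base, drifted]), 110.0, time_lapse=True)
        _, shifts = pc.register_translation_stack(stack)
        assert np.allclose(shifts[1], (3, -2), atol=0.05)

    def test_subpixel_drift_recovered(self):
        base = self._scene()
        drifted = ndshift(base, (0.5, 0.5), order=3, mode="nearest")
        stack = pc.ImageStack(np.stack([base, drifted]), 110.0, time_lapse=True)
        _, shifts = pc.register_translation_stack(stack)
        assert np.allclose(shifts[1], (0.5, 0.5), atol=0.1)

    def test_identical_frames_zero_shift(self):
        base = self._scene()
        stack = pc.ImageStack(np.stack([base, base]), 110.0, time_lapse=True)
        aligned, shifts = pc.register_translation_stack(stack)
        assert np.allclose(shifts, 0.0)
        assert np.allclose(aligned.data[1], base)
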