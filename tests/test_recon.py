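import numpy as np
import pytest

from bonespect.grid import VoxelGrid
from bonespect.phantoms import make_cylinder_phantom
from bonespect.projector import (Geometry, RotationSet, Sinogram,
                                 forward_project, simulate_scatter_window)
from bonespect.recon import (ReconCondition, ReconConfigError, chang_uac,
                             dew_scatter_correct, gaussian_postfilter, osem,
                             reconstruct_condition)
from oracles import ray_march_path_length


def sino(main, sub=None, geo=None):
    geo = geo or Geometry(n_views=main.shape[0])
    return Sinogram(main, geo, (6.0, 6.0, 6.0), sub=sub)


class TestDewScatterCorrection:
    def test_zero_sub_window_leaves_main_untouched(self):
        s = sino(np.full((12, 8, 2), 100.0), sub=np.zeros((12, 8, 2)))
        out = dew_scatter_correct(s)
        assert np.array_equal(out.main, s.main)

    def test_window_width_arithmetic(self):
        # main 100, sub 20, k=0.5, width ratio 28.2/12 -> 100 - 23.5 = 76.5
        s = sino(np.full((4, 2, 1), 100.0), sub=np.full((4, 2, 1), 20.0))
        out = dew_scatter_correct(s, k=0.5)
        assert out.main == pytest.approx(np.full((4, 2, 1), 76.5))

    def test_overestimate_clipped_at_zero(self):
        s = sino(np.full((4, 2, 1), 10.0), sub=np.full((4, 2, 1), 50.0))
        assert np.all(dew_scatter_correct(s).main == 0.0)

    def test_missing_sub_window_rejected(self):
        with pytest.raises(ReconConfigError):
            dew_scatter_correct(sino(np.ones((4, 2, 1))))


class TestOsem:
    def test_zero_sinogram_returns_zero_volume_with_warning(self):
        s = sino(np.zeros((12, 16, 2)))
        with pytest.warns(UserWarning, match="all-zero"):
            vol = osem(s, iterations=2, subsets=4)
        assert not vol.data.any()

    def test_subsets_must_divide_views(self):
        with pytest.raises(ValueError, match="divide"):
            osem(sino(np.ones((12, 8, 1))), subsets=5)

    def test_uniform_cylinder_interior_recovered_within_5pct(self):
        # noiseless, unattenuated: OSEM must recover the interior mean
        from scipy.ndimage import binary_erosion
        truth = make_cylinder_phantom(activity_conc=8000.0)
        geo = Geometry(sensitivity_cps_per_bq=1e-4)
        s = forward_project(truth.activity, None, geo, psf_enabled=False)
        vol = osem(s, iterations=10, subsets=10, track_residuals=True)
        # recovered counts/cc correspond to conc * t_view * sensitivity
        expected = 8000.0 * geo.t_view_s * geo.sensitivity_cps_per_bq
        interior = binary_erosion(truth.masks["body"], iterations=1)
        mean = vol.data[interior].mean()
        assert mean == pytest.approx(expected, rel=0.05)
        # L1 forward-projection residual non-increasing on noiseless data
        res = vol.meta["residuals_l1"]
        assert all(b <= a * (1 + 1e-9) for a, b in zip(res, res[1:]))


class TestChang:
    def _disk(self, n=16, radius_vox=6.0, spacing=10.0):
        xs = np.arange(n) - (n - 1) / 2.0
        mask2d = (xs[:, None] ** 2 + xs[None, :] ** 2) <= radius_vox ** 2
        mask = mask2d[:, :, None]
        vol = VoxelGrid(np.ones((n, n, 1)), (spacing,) * 3, "count_density")
        return vol, mask

    def test_mu0_zero_is_identity(self):
        vol, mask = self._disk()
        out = chang_uac(vol, mask, 0.0)
        assert np.array_equal(out.data, vol.data)

    def test_center_of_disk_matches_closed_form(self):
        # all paths from the centre have length R -> C = exp(mu0 * R)
        n, sp, rad_vox = 41, 5.0, 17.2
        vol, mask = self._disk(n, rad_vox, sp)
        r_cm = rad_vox * sp / 10.0          # 8.6 cm disk radius
        for mu0 in (0.11, 0.2):
            out = chang_uac(vol, mask, mu0, n_angles=120)
            c = out.data[n // 2, n // 2, 0]
            assert c == pytest.approx(np.exp(mu0 * r_cm), rel=0.01)

    def test_correction_at_least_one_everywhere(self):
        vol, mask = self._disk()
        out = chang_uac(vol, mask, 0.15)
        assert np.all(out.data >= 1.0 - 1e-12)
        assert np.array_equal(out.data[~mask], vol.data[~mask])

    def test_matches_ray_march_oracle_on_arbitrary_mask(self, rng):
        # irregular 16x16 mask: per-voxel correction vs brute-force marching
        n, sp = 16, 8.0
        xs = np.arange(n) - (n - 1) / 2.0
        blob = ((xs[:, None] / 6.0) ** 2 + (xs[None, :] / 4.5) ** 2) <= 1.0
        mask = blob[:, :, None]
        vol = VoxelGrid(np.ones((n, n, 1)), (sp,) * 3, "count_density")
        mu0, n_ang = 0.13, 24
        out = chang_uac(vol, mask, mu0, n_angles=n_ang)
        angles = np.arange(n_ang) * 360.0 / n_ang
        mf = blob.astype(float)
        for i in range(4, 12):
            for j in range(4, 12):
                if not blob[i, j]:
                    continue
                ts = [np.exp(-mu0 * ray_march_path_length(mf, i, j, a, sp))
                      for a in angles]
                c_ref = max(n_ang / np.sum(ts), 1.0)
                assert out.data[i, j, 0] == pytest.approx(c_ref, rel=0.05)

    def test_empty_mask_rejected(self):
        vol, _ = self._disk()
        with pytest.raises(ValueError, match="empty"):
            chang_uac(vol, np.zeros(vol.shape, bool), 0.11)


class TestPostfilter:
    def test_zero_fwhm_is_identity(self, rng):
        vol = VoxelGrid(rng.random((8, 8, 4)), (4.0, 4.0, 4.0), "count_density")
        assert np.array_equal(gaussian_postfilter(vol, 0.0).data, vol.data)

    def test_total_sum_preserved(self, rng):
        vol = VoxelGrid(rng.random((16, 16, 8)), (4.42, 4.42, 4.42),
                        "count_density")
        out = gaussian_postfilter(vol, 3.0)
        assert out.data.sum() == pytest.approx(vol.data.sum(), rel=1e-6)

    def test_delta_input_has_nominal_fwhm(self):
        vol = VoxelGrid(np.zeros((33, 33, 1)), (1.0, 1.0, 1.0), "count_density")
        vol.data[16, 16, 0] = 1.0
        fwhm = 6.0
        prof = gaussian_postfilter(vol, fwhm).data[:, 16, 0]
        half = prof.max() / 2.0
        above = np.flatnonzero(prof >= half)
        # linear interpolation of the half crossings
        lo = above[0] - (prof[above[0]] - half) / (prof[above[0]] - prof[above[0] - 1])
        hi = above[-1] + (prof[above[-1]] - half) / (prof[above[-1]] - prof[above[-1] + 1])
        assert hi - lo == pytest.approx(fwhm, abs=0.5)

    def test_negative_fwhm_rejected(self, rng):
        vol = VoxelGrid(np.ones((4, 4, 2)), (4.0, 4.0, 4.0), "count_density")
        with pytest.raises(ValueError):
            gaussian_postfilter(vol, -1.0)


class TestConditions:
    def test_presets_encode_the_study_design(self):
        ctac = ReconCondition.preset("CTAC")
        assert (ctac.iterations, ctac.subsets, ctac.postfilter_fwhm_mm) == (10, 10, 3.0)
        seg = ReconCondition.preset("SEG")
        assert (seg.iterations, seg.subsets, seg.postfilter_fwhm_mm) == (5, 10, 4.0)
        nc = ReconCondition.preset("NC")
        assert (nc.ac, nc.sc, nc.rr) == ("none", False, False)
        acm = ReconCondition.preset("AC_MINUS")
        assert (acm.ac, acm.sc, acm.rr) == ("none", True, True)
        with pytest.raises(ReconConfigError):
            ReconCondition.preset("XYZ")

    def test_missing_mu_map_rejected(self):
        s = sino(np.ones((60, 16, 1)), sub=np.zeros((60, 16, 1)))
        with pytest.raises(ReconConfigError, match="mu-map"):
            reconstruct_condition(s, ReconCondition.preset("CTAC"))

    def test_same_inputs_same_condition_reproducible(self):
        geo = Geometry(sensitivity_cps_per_bq=1e-4)
        truth = make_cylinder_phantom(activity_conc=5000.0)
        s = forward_project(truth.activity, None, geo, psf_enabled=False)
        s = simulate_scatter_window(s, 0.2)
        rot = RotationSet(truth.ct.shape[:2], geo.angles_deg)
        cond = ReconCondition.preset("AC_MINUS")
        a = reconstruct_condition(s, cond, rotations=rot)
        b = reconstruct_condition(s, cond, rotations=rot)
        assert np.array_equal(a.data, b.data)
        assert a.meta["condition"] == "AC_MINUS"
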