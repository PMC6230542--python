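"""Attenuation model, projector and OSEM reconstruction oracles."""

import numpy as np
import pytest
from dataclasses import replace

from pseudoct.phantom import ActivityMap, CTVolume
from pseudoct.physics import (
    CoverageError, MU_WATER_DEFAULT, MuMap, ReconConfig, ScanGeometry,
    Sinogram, apply_post_filter, ct_to_mu, default_geometry, forward_project,
    reconstruct_osem, system_matrix, PETImage)

PX = 2.0  # mm
SPACING = (PX, PX, PX)


def _vol(arr2d, n_slices=1):
    return np.repeat(np.asarray(arr2d, dtype=float)[..., None], n_slices, axis=2)


class TestCtToMu:
    def test_air_and_water_endpoints(self):
        ct = CTVolume(voxels=_vol(np.array([[-1000.0, 0.0]])), spacing=SPACING)
        mu = ct_to_mu(ct)
        assert mu.voxels[0, 0, 0] == 0.0
        assert mu.voxels[0, 1, 0] == pytest.approx(MU_WATER_DEFAULT)

    def test_two_segment_values_strictly_increase(self):
        hus = np.array([[-500.0, 0.0, 500.0, 1500.0]])
        mu = ct_to_mu(CTVolume(voxels=_vol(hus), spacing=SPACING))
        vals = mu.voxels[0, :, 0]
        assert (np.diff(vals) > 0).all()
        # direct evaluation of the two linear segments
        assert vals[0] == pytest.approx(MU_WATER_DEFAULT * 0.5)
        assert vals[2] == pytest.approx(MU_WATER_DEFAULT + 5.0e-5 * 500)

    def test_monotone_over_random_pairs(self, rng):
        hu = rng.uniform(-1024, 3000, size=(50, 2))
        hu.sort(axis=1)
        ct = CTVolume(voxels=hu[:, :, None], spacing=SPACING)
        mu = ct_to_mu(ct).voxels
        assert (mu[:, 1, 0] >= mu[:, 0, 0]).all()

    def test_nonfinite_named_slice(self):
        bad = np.zeros((4, 4, 3))
        bad[1, 1, 2] = np.nan
        ct = CTVolume.__new__(CTVolume)  # bypass clamping to keep the NaN
        ct.voxels, ct.spacing, ct.origin = bad, SPACING, (0, 0, 0)
        with pytest.raises(ValueError, match="2"):
            ct_to_mu(ct)


class TestForwardProject:
    def test_zero_activity_gives_zero_sinogram(self, rng):
        act = ActivityMap(voxels=np.zeros((16, 16, 2)), spacing=SPACING)
        geom = default_geometry(16, PX)
        sino = forward_project(act, None, geom)
        assert (sino.counts == 0).all()

    def test_zero_mu_equals_no_mu(self, rng):
        act_v = rng.uniform(0, 10, size=(16, 16, 1))
        act = ActivityMap(voxels=act_v, spacing=SPACING)
        geom = default_geometry(16, PX)
        s1 = forward_project(act, None, geom)
        s2 = forward_project(act, MuMap(np.zeros_like(act_v), SPACING), geom)
        np.testing.assert_allclose(s1.counts, s2.counts)

    def test_single_pixel_attenuated_ray_matches_line_integral(self):
        """Axis-aligned ray through one hot pixel under a uniform slab:
        expected count = scale · a · l · exp(−μ t)."""
        n = 32
        geom = default_geometry(n, PX)
        a, mu_val = 7.0, 0.096
        r_pix, c_pix = 10, 16
        act_v = np.zeros((n, n, 1))
        act_v[r_pix, c_pix, 0] = a
        slab_rows = slice(18, 26)  # 8 rows => t = 8 · 0.2 cm
        mu_v = np.zeros((n, n, 1))
        mu_v[slab_rows, :, 0] = mu_val
        sino = forward_project(ActivityMap(act_v, SPACING),
                               MuMap(mu_v, SPACING), geom, count_scale=3.0)
        # view at angle 0 integrates along image rows (constant column)
        s_mm = (c_pix - (n - 1) / 2.0) * PX
        b = int(round(s_mm / geom.bin_width + (geom.n_bins - 1) / 2.0))
        l_cm = PX / 10.0
        t_cm = 8 * l_cm
        expected = 3.0 * a * l_cm * np.exp(-mu_val * t_cm)
        assert sino.counts[0, b, 0] == pytest.approx(expected, rel=0.01)

    def test_linearity_in_activity(self, rng):
        geom = default_geometry(16, PX)
        a1 = rng.uniform(0, 5, size=(16, 16, 1))
        a2 = rng.uniform(0, 5, size=(16, 16, 1))
        mu = MuMap(rng.uniform(0, 0.1, size=(16, 16, 1)), SPACING)
        f = lambda v: forward_project(ActivityMap(v, SPACING), mu, geom).counts
        np.testing.assert_allclose(f(a1 + a2), f(a1) + f(a2), rtol=1e-10)

    def test_poisson_noise_is_seeded_and_integer(self, rng):
        act = ActivityMap(voxels=rng.uniform(0, 50, size=(16, 16, 1)),
                          spacing=SPACING)
        geom = default_geometry(16, PX)
        s1 = forward_project(act, None, geom, count_scale=10, seed=5)
        s2 = forward_project(act, None, geom, count_scale=10, seed=5)
        assert s1.noise_realized
        np.testing.assert_array_equal(s1.counts, s2.counts)
        assert np.allclose(s1.counts, np.round(s1.counts))

    def test_coverage_error_when_bins_too_few(self, rng):
        act = ActivityMap(voxels=np.ones((32, 32, 1)), spacing=SPACING)
        geom = ScanGeometry(n_angles=8, n_bins=10, bin_width=PX)
        with pytest.raises(CoverageError):
            forward_project(act, None, geom)


class TestOsem:
    def test_all_zero_sinogram_reconstructs_to_zero(self):
        geom = default_geometry(16, PX)
        sino = Sinogram(np.zeros((geom.n_angles, geom.n_bins, 1)), geom)
        cfg = ReconConfig(n_iterations=1, n_subsets=1, post_filter_fwhm=0,
                          use_attenuation=False)
        img = reconstruct_osem(sino, None, cfg, grid_size=16, pixel_size=PX)
        assert (img.voxels == 0).all()

    def test_subsets_must_divide_angles(self):
        geom = ScanGeometry(n_angles=10, n_bins=30, bin_width=PX)
        sino = Sinogram(np.zeros((10, 30, 1)), geom)
        cfg = ReconConfig(n_subsets=3, use_attenuation=False)
        with pytest.raises(ValueError, match="divide"):
            reconstruct_osem(sino, None, cfg, grid_size=16, pixel_size=PX)

    def test_noiseless_point_source_localizes_exactly(self):
        n = 24
        geom = default_geometry(n, PX, n_angles=60)
        act = np.zeros((n, n, 1))
        act[14, 9, 0] = 5.0
        sino = forward_project(ActivityMap(act, SPACING), None, geom)
        cfg = ReconConfig(n_iterations=50, n_subsets=1, post_filter_fwhm=0,
                          use_attenuation=False)
        img = reconstruct_osem(sino, None, cfg, grid_size=n, pixel_size=PX)
        assert np.unravel_index(np.argmax(img.voxels[..., 0]),
                                (n, n)) == (14, 9)

    def test_total_activity_matches_sinogram_counts(self):
        """With a matched projector pair the MLEM update conserves the
        measured counts: Σ x · sens = Σ y, so total activity is pinned."""
        n = 24
        geom = default_geometry(n, PX, n_angles=60)
        rr, cc = np.meshgrid(*[np.arange(n) - (n - 1) / 2] * 2, indexing="ij")
        disc = ((rr**2 + cc**2) <= 64).astype(float) * 3.0
        act = ActivityMap(disc[..., None], SPACING)
        sino = forward_project(act, None, geom, count_scale=2.0)
        cfg = ReconConfig(n_iterations=30, n_subsets=1, post_filter_fwhm=0,
                          use_attenuation=False)
        img = reconstruct_osem(sino, None, cfg, grid_size=n, pixel_size=PX)
        implied = sino.counts.sum() / (2.0 * geom.n_angles * PX / 10.0)
        assert img.voxels.sum() == pytest.approx(implied, rel=1e-3)

    def test_loglik_nondecreasing_on_noiseless_data(self):
        n = 24
        geom = default_geometry(n, PX, n_angles=60)
        rr, cc = np.meshgrid(*[np.arange(n) - (n - 1) / 2] * 2, indexing="ij")
        disc = ((rr / 8.0)**2 + (cc / 6.0)**2 <= 1).astype(float) * 4.0
        mu = MuMap((disc[..., None] > 0) * 0.09, SPACING)
        sino = forward_project(ActivityMap(disc[..., None], SPACING), mu, geom)
        cfg = ReconConfig(n_iterations=15, n_subsets=1, post_filter_fwhm=0,
                          track_loglik=True)
        img = reconstruct_osem(sino, mu, cfg)
        ll = np.array(img.loglik_trace[0])
        assert (np.diff(ll) >= -1e-6 * np.abs(ll[:-1])).all()

    def test_end_to_end_recovery_improves_with_iterations(self):
        n = 24
        geom = default_geometry(n, PX, n_angles=60)
        rr, cc = np.meshgrid(*[np.arange(n) - (n - 1) / 2] * 2, indexing="ij")
        truth = np.exp(-((rr / 5.0)**2 + (cc / 4.0)**2))[..., None] * 10.0
        mu = MuMap((truth > 1.0) * 0.09, SPACING)
        sino = forward_project(ActivityMap(truth, SPACING), mu, geom)
        def nrmse(n_it):
            cfg = ReconConfig(n_iterations=n_it, n_subsets=1, post_filter_fwhm=0)
            img = reconstruct_osem(sino, mu, cfg)
            return np.sqrt(((img.voxels - truth)**2).mean()) / truth.max()
        assert nrmse(40) < nrmse(4) < nrmse(1)
        assert nrmse(40) < 0.05


class TestPostFilter:
    def test_zero_fwhm_is_identity(self, rng):
        img = PETImage(rng.uniform(0, 5, size=(8, 8, 2)), SPACING)
        out = apply_post_filter(img, 0.0)
        np.testing.assert_array_equal(out.voxels, img.voxels)

    def test_delta_sum_preserved_and_peak_stays(self):
        v = np.zeros((33, 33, 17))
        v[16, 16, 8] = 10.0
        img = PETImage(v, (1.0, 1.0, 1.0))
        out = apply_post_filter(img, 4.0)
        assert out.voxels.sum() == pytest.approx(10.0, rel=1e-6)
        assert np.unravel_index(np.argmax(out.voxels), v.shape) == (16, 16, 8)


def test_system_matrix_preserves_mass_per_view():
    geom = default_geometry(16, PX, n_angles=12)
    A = system_matrix(16, PX, geom)
    img = np.random.default_rng(0).uniform(0, 1, size=16 * 16)
    p = (A @ img).reshape(geom.n_angles, geom.n_bins)
    np.testing.assert_allclose(p.sum(axis=1), img.sum() * PX / 10.0, rtol=1e-12)
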