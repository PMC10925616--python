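"""Acquisition simulator: conservation, attenuation, noise, offsets."""

import numpy as np
import pytest

from spectdose.phantoms import build_point_sources, make_grid
from spectdose.simulate import (
    AcquisitionConfig,
    ProjectionSet,
    RigidOffset,
    apply_offset,
    default_window_splits,
    simulate_acquisition,
)


def _vacuum(grid):
    return grid.like(np.zeros(grid.shape), "mu_per_mm")


class TestSimulateAcquisition:
    def test_vacuum_point_source_conserves_counts_per_view(self, nm_grid16, small_cfg):
        """No attenuation, scatter, blur or noise: every view's total count
        rate equals sensitivity x activity."""
        act = build_point_sources([[0.0, 0.0, 0.0]], 2.0, nm_grid16)
        proj = simulate_acquisition(act, _vacuum(nm_grid16), small_cfg)
        per_view = proj.windows["main"].sum(axis=(1, 2)) / small_cfg.duration_s
        expected = small_cfg.sensitivity_cps_per_MBq * 2.0
        assert np.allclose(per_view, expected, rtol=1e-9)

    def test_beer_lambert_attenuation(self):
        """A slab of water-like attenuation reduces view-0 counts by
        exp(-mu L) with L the centre-to-exit path, matching the closed form."""
        n = 32
        grid = make_grid((n, n, n), (4.42, 4.42, 4.42), "NM")
        mu = grid.like(np.zeros(grid.shape), "mu_per_mm")
        mu.data[:, 10:20, :] = 0.0136
        act = grid.like(np.zeros(grid.shape))
        act.data[16, 15, 16] = 1.0
        cfg = AcquisitionConfig(
            n_angles=2, det_pixels=(n, n), noise=False, scatter_fraction=0.0, psf_sigma_mm=0.0
        )
        proj = simulate_acquisition(act, mu, cfg)
        got = proj.windows["main"][0].sum() / (cfg.duration_s * cfg.sensitivity_cps_per_MBq)
        path_mm = (4 + 0.5) * 4.42  # 4 full voxels above the source plus half itself
        assert got == pytest.approx(np.exp(-0.0136 * path_mm), rel=0.01)

    def test_fixed_seed_bit_identical(self, nm_grid16):
        act = build_point_sources([[2.0, -3.0, 1.0]], 5.0, nm_grid16)
        cfg = AcquisitionConfig(n_angles=8, det_pixels=(16, 16), noise=True, seed=42)
        a = simulate_acquisition(act, _vacuum(nm_grid16), cfg)
        b = simulate_acquisition(act, _vacuum(nm_grid16), cfg)
        for w in a.windows:
            assert np.array_equal(a.windows[w], b.windows[w])

    def test_noise_free_linearity(self, nm_grid16, small_cfg):
        act = build_point_sources([[2.0, -3.0, 1.0], [-8.0, 4.0, -2.0]], 1.0, nm_grid16)
        scaled = act.like(3.0 * act.data)
        p1 = simulate_acquisition(act, _vacuum(nm_grid16), small_cfg)
        p3 = simulate_acquisition(scaled, _vacuum(nm_grid16), small_cfg)
        assert np.allclose(p3.windows["main"], 3.0 * p1.windows["main"], rtol=1e-9)

    def test_poisson_mean_converges_to_noise_free(self, nm_grid16):
        """Sample mean over 1000 noise realizations matches the noise-free
        sinogram: total within 3 SE, and per-pixel 3-SE violations rare."""
        act = build_point_sources([[0.0, 0.0, 0.0]], 20.0, nm_grid16)
        base = AcquisitionConfig(
            n_angles=4, det_pixels=(16, 16), noise=False, psf_sigma_mm=6.0, scatter_fraction=0.3
        )
        clean = simulate_acquisition(act, _vacuum(nm_grid16), base).windows["main"]
        total = np.zeros_like(clean, dtype=float)
        n_seeds = 1000
        for seed in range(n_seeds):
            cfg = AcquisitionConfig(
                n_angles=4, det_pixels=(16, 16), noise=True, psf_sigma_mm=6.0,
                scatter_fraction=0.3, seed=seed,
            )
            total += simulate_acquisition(act, _vacuum(nm_grid16), cfg).windows["main"]
        mean = total / n_seeds
        se_total = np.sqrt(clean.sum() / n_seeds)
        assert abs(mean.sum() - clean.sum()) < 3 * se_total
        hot = clean > 5.0
        se_pix = np.sqrt(clean[hot] / n_seeds)
        violations = np.abs(mean[hot] - clean[hot]) > 3 * se_pix
        assert violations.mean() < 0.02

    def test_grid_mismatch_rejected(self, nm_grid16, small_cfg):
        act = build_point_sources([[0.0, 0.0, 0.0]], 1.0, nm_grid16)
        other = make_grid((8, 8, 8), (4.42, 4.42, 4.42), "NM")
        with pytest.raises(ValueError, match="share"):
            simulate_acquisition(act, _vacuum(other), small_cfg)

    def test_negative_activity_rejected(self, nm_grid16, small_cfg):
        act = nm_grid16.like(np.full(nm_grid16.shape, -1.0))
        with pytest.raises(ValueError, match="negative"):
            simulate_acquisition(act, _vacuum(nm_grid16), small_cfg)

    def test_window_splits_sum_to_one(self):
        assert sum(default_window_splits().values()) == pytest.approx(1.0)

    def test_save_load_round_trip(self, nm_grid16, small_cfg, tmp_path):
        act = build_point_sources([[0.0, 0.0, 0.0]], 1.0, nm_grid16)
        proj = simulate_acquisition(act, _vacuum(nm_grid16), small_cfg)
        path = tmp_path / "proj.npz"
        proj.save(path)
        back = ProjectionSet.load(path)
        assert np.allclose(back.windows["main"], proj.windows["main"])
        assert back.duration_s == proj.duration_s


class TestApplyOffset:
    def test_zero_offset_identity(self, nm_grid16):
        act = build_point_sources([[1.0, 2.0, 3.0]], 1.0, nm_grid16)
        out = apply_offset(act, RigidOffset(0, 0, 0))
        assert np.allclose(out.data, act.data, atol=1e-12)

    def test_integer_voxel_offset_exact(self, nm_grid16):
        act = build_point_sources([[0.0, 0.0, 0.0]], 1.0, nm_grid16)
        out = apply_offset(act, RigidOffset(4.42, -4.42, 8.84))
        assert np.allclose(out.data, np.roll(act.data, (1, -1, 2), axis=(0, 1, 2)), atol=1e-12)

    def test_centroid_moves_by_offset(self, nm_grid16):
        act = build_point_sources([[1.0, -2.0, 0.5]], 1.0, nm_grid16)
        off = RigidOffset(3.1, 0.9, 1.2)
        out = apply_offset(act, off)
        moved = out.centroid() - act.centroid()
        assert np.abs(moved - off.as_array()).max() < 0.05

    def test_spectral_round_trip_on_band_limited_volume(self, nm_grid16):
        """Offset followed by its negation is the identity to <1e-6 of the
        peak for band-limited content (spectral shift)."""
        from scipy import ndimage

        data = np.zeros(nm_grid16.shape)
        data[8, 8, 8] = 1.0
        # exact spectral Gaussian: band-limited to roundoff at this width
        smooth = nm_grid16.like(
            np.fft.ifftn(ndimage.fourier_gaussian(np.fft.fftn(data), 2.5)).real
        )
        off = RigidOffset(1.3, -0.7, 2.1)
        back = apply_offset(apply_offset(smooth, off, "fourier"), off.negated(), "fourier")
        err = np.abs(back.data - smooth.data).max()
        assert err < 1e-6 * smooth.data.max()

    def test_linear_round_trip_on_smooth_volume(self, nm_grid16):
        from scipy import ndimage

        data = np.zeros(nm_grid16.shape)
        data[8, 8, 8] = 1.0
        smooth = nm_grid16.like(ndimage.gaussian_filter(data, 2.5))
        off = RigidOffset(1.3, -0.7, 2.1)
        back = apply_offset(apply_offset(smooth, off), off.negated())
        inner = np.s_[3:-3, 3:-3, 3:-3]
        err = np.abs(back.data[inner] - smooth.data[inner]).max()
        assert err < 0.1 * smooth.data.max()

    def test_non_finite_offset_rejected(self):
        with pytest.raises(ValueError):
            RigidOffset(np.nan, 0.0, 0.0)
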