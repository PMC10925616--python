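"""TEW correction, MLEM reconstruction, calibration and sphere recovery."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

from spectdose.phantoms import (
    PhantomSpec,
    build_jaszczak,
    build_nema,
    build_point_sources,
    jaszczak_mask,
    make_grid,
    nema_sphere_masks,
)
from spectdose.projector import ParallelProjector
from spectdose.recon import (
    CalibrationFactor,
    activity_from_counts,
    compute_cf,
    dilate_mask_mm,
    mlem_reconstruct,
    sphere_recovery,
    tew_correct,
)
from spectdose.simulate import AcquisitionConfig, ProjectionSet, simulate_acquisition
from spectdose.volume import resample


def _proj_set(main, lower, upper, angles=None):
    main = np.atleast_3d(np.asarray(main, dtype=float))
    if angles is None:
        angles = np.arange(main.shape[0]) * 360.0 / main.shape[0]
    return ProjectionSet(
        windows={
            "main": main,
            "lower_scatter": np.broadcast_to(lower, main.shape).copy(),
            "upper_scatter": np.broadcast_to(upper, main.shape).copy(),
        },
        angles_deg=np.asarray(angles, dtype=float),
        duration_s=30.0,
        det_spacing_mm=4.42,
    )


class TestTEW:
    def test_no_scatter_counts_leaves_main_unchanged(self):
        main = np.arange(24.0).reshape(2, 3, 4)
        out = tew_correct(_proj_set(main, 0.0, 0.0))
        assert np.array_equal(out, main)

    def test_trapezoid_formula_plug_in(self):
        """C_lower = 17.8 and C_upper = 24 (one count per keV in each flank)
        estimate exactly one count per keV across the 41.6-keV photopeak."""
        out = tew_correct(_proj_set(np.full((1, 1, 1), 100.0), 17.8, 24.0))
        assert out[0, 0, 0] == pytest.approx(100.0 - 41.6, abs=1e-12)

    def test_clamped_at_zero(self):
        out = tew_correct(_proj_set(np.full((1, 1, 1), 10.0), 1000.0, 1000.0))
        assert out[0, 0, 0] == 0.0

    def test_missing_window_rejected(self):
        ps = _proj_set(np.ones((1, 2, 2)), 1.0, 1.0)
        del ps.windows["upper_scatter"]
        with pytest.raises(ValueError, match="upper_scatter"):
            tew_correct(ps)

    @settings(derandomize=True, max_examples=30)
    @given(
        sinos=hnp.arrays(
            float,
            (3, 2, 4, 4),
            elements=st.floats(0, 1e4, allow_nan=False),
        )
    )
    def test_elementwise_scalar_oracle(self, sinos):
        """TEW equals the per-pixel scalar trapezoid applied elementwise."""
        out = tew_correct(_proj_set(sinos[0], sinos[1], sinos[2]))
        for idx in np.ndindex(sinos[0].shape):
            expected = max(
                sinos[0][idx] - (sinos[1][idx] / 17.8 + sinos[2][idx] / 24.0) * 41.6 / 2.0,
                0.0,
            )
            assert out[idx] == pytest.approx(expected, rel=1e-12, abs=1e-12)


class TestMLEM:
    def test_all_zero_sinogram_gives_zero_image(self, nm_grid16, small_cfg):
        mu = nm_grid16.like(np.zeros(nm_grid16.shape), "mu_per_mm")
        out = mlem_reconstruct(
            np.zeros((small_cfg.n_angles, 16, 16)), mu, small_cfg, iterations=2, subsets=1
        )
        assert not out.data.any()

    def test_hot_voxel_mass_concentrates(self, nm_grid16, small_cfg):
        """Inverse crime on a single hot voxel in vacuum: >=95% of the
        reconstructed counts land in its 3x3x3 neighbourhood."""
        act = nm_grid16.like(np.zeros(nm_grid16.shape))
        act.data[8, 8, 8] = 5.0
        mu = nm_grid16.like(np.zeros(nm_grid16.shape), "mu_per_mm")
        proj = simulate_acquisition(act, mu, small_cfg)
        rec = mlem_reconstruct(proj.windows["main"], mu, small_cfg, iterations=20, subsets=1)
        frac = rec.data[7:10, 7:10, 7:10].sum() / rec.data.sum()
        assert frac >= 0.95

    def test_count_conservation_and_monotone_nll(self, nm_grid32):
        """Forward-projecting the reconstruction reproduces the measured
        counts within 1%, and the Poisson NLL never increases (noise-free)."""
        cfg = AcquisitionConfig(
            n_angles=16, det_pixels=(32, 32), noise=False, scatter_fraction=0.0, psf_sigma_mm=4.0
        )
        act, mu = build_jaszczak(2.0, 60.0, 60.0, grid=nm_grid32)
        proj = simulate_acquisition(act, mu, cfg)
        trace: list = []
        rec = mlem_reconstruct(
            proj.windows["main"], mu, cfg, iterations=15, subsets=1, nll_trace=trace
        )
        p = ParallelProjector(
            resample(mu, cfg.nm_grid()).data, (4.42, 4.42, 4.42), cfg.angles_deg, 4.0
        )
        refit = p.forward(rec.data * cfg.duration_s).sum()
        measured = proj.windows["main"].sum()
        assert refit == pytest.approx(measured, rel=0.01)
        diffs = np.diff(trace)
        assert (diffs <= 1e-9 * abs(trace[0])).all()

    def test_duration_invariance_of_cps_image(self, nm_grid16):
        """Doubling the view duration doubles counts but leaves the cps
        reconstruction unchanged."""
        act = build_point_sources([[0.0, 0.0, 0.0]], 3.0, nm_grid16)
        mu = nm_grid16.like(np.zeros(nm_grid16.shape), "mu_per_mm")
        recs = []
        for dur in (30.0, 60.0):
            cfg = AcquisitionConfig(
                n_angles=12, det_pixels=(16, 16), noise=False, scatter_fraction=0.0,
                psf_sigma_mm=0.0, duration_s=dur,
            )
            proj = simulate_acquisition(act, mu, cfg)
            recs.append(mlem_reconstruct(proj.windows["main"], mu, cfg, iterations=5, subsets=2))
        assert np.allclose(recs[0].data, recs[1].data, rtol=1e-6, atol=1e-9)

    def test_geometry_mismatch_rejected(self, nm_grid16, small_cfg):
        mu = nm_grid16.like(np.zeros(nm_grid16.shape), "mu_per_mm")
        with pytest.raises(ValueError, match="sinogram shape"):
            mlem_reconstruct(np.zeros((3, 5, 5)), mu, small_cfg)


class TestCalibrationFactor:
    def _cylinder_recon(self, activity_mCi, cfg=None):
        cfg = cfg or AcquisitionConfig(
            n_angles=24, det_pixels=(32, 32), noise=False, scatter_fraction=0.0, psf_sigma_mm=4.5
        )
        grid = make_grid((40, 40, 40), (3.5, 3.5, 3.5), "CT")
        act, mu = build_jaszczak(activity_mCi, 100.0, 100.0, grid=grid)
        proj = simulate_acquisition(act, mu, cfg)
        rec = mlem_reconstruct(proj.windows["main"], mu, cfg, iterations=10, subsets=4)
        mask = resample(jaszczak_mask(100.0, 100.0, grid), rec)
        return rec, dilate_mask_mm(mask, 10.0), cfg

    def test_closed_loop_recovers_system_sensitivity(self):
        """Scatter off, perfect reconstruction: the measured CF equals the
        simulated per-view sensitivity within 5%."""
        rec, voi, cfg = self._cylinder_recon(5.0)
        cf = compute_cf(rec, voi, 5.0 * 37.0)
        assert cf.value_cps_per_MBq == pytest.approx(cfg.sensitivity_cps_per_MBq, rel=0.05)

    def test_intensive_in_activity(self):
        rec1, voi, _ = self._cylinder_recon(5.0)
        rec2, _, _ = self._cylinder_recon(10.0)
        cf1 = compute_cf(rec1, voi, 5.0 * 37.0)
        cf2 = compute_cf(rec2, voi, 10.0 * 37.0)
        assert cf2.value_cps_per_MBq == pytest.approx(cf1.value_cps_per_MBq, rel=1e-6)

    def test_round_trip_activity_recovery(self):
        rec, voi, _ = self._cylinder_recon(5.0)
        cf = compute_cf(rec, voi, 5.0 * 37.0)
        cps = rec.data[np.asarray(voi.data, bool)].sum()
        assert activity_from_counts(cps, cf) == pytest.approx(5.0, rel=0.05)

    def test_zero_activity_rejected(self, nm_grid16):
        rec = nm_grid16.like(np.ones(nm_grid16.shape), "cps")
        voi = nm_grid16.like(np.ones(nm_grid16.shape, bool), "mask")
        with pytest.raises(ValueError, match="positive"):
            compute_cf(rec, voi, 0.0)
        with pytest.raises(ValueError):
            CalibrationFactor(-1.0)


class TestActivityFromCounts:
    CF = CalibrationFactor(5.124969, phantom_id="uniform-cylinder")

    @pytest.mark.parametrize(
        "cps, expected_mCi",
        [(251.6, 1.33), (109.5, 0.58), (51.5, 0.27)],
    )
    def test_sphere_count_rates_convert_to_reported_activities(self, cps, expected_mCi):
        assert round(activity_from_counts(cps, self.CF), 2) == expected_mCi

    def test_zero_counts_zero_activity(self):
        assert activity_from_counts(0.0, self.CF) == 0.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            activity_from_counts(-1.0, self.CF)


class TestSphereRecovery:
    def test_margin_zero_inverse_crime(self, compact_nema_spec, nm_grid32):
        """Truth supported exactly on the contour voxels, no blur/scatter/
        noise, converged MLEM: every sphere recovers within 2% at margin 0."""
        contours = nema_sphere_masks(compact_nema_spec, nm_grid32)
        act = nm_grid32.like(np.zeros(nm_grid32.shape))
        for s, m in contours:
            mask = np.asarray(m.data, bool)
            act.data[mask] += s.activity_mCi * 37.0 / mask.sum()
        _, mu = build_nema(compact_nema_spec, nm_grid32)
        cfg = AcquisitionConfig(
            n_angles=24, det_pixels=(32, 32), noise=False, scatter_fraction=0.0, psf_sigma_mm=0.0
        )
        proj = simulate_acquisition(act, mu, cfg)
        rec = mlem_reconstruct(proj.windows["main"], mu, cfg, iterations=40, subsets=4)
        cf = CalibrationFactor(cfg.sensitivity_cps_per_MBq)
        rows = sphere_recovery(rec, contours, cf, margin_mm=0.0)
        assert max(abs(r.pct_diff) for r in rows) <= 2.0

    def test_end_to_end_linearity(self, compact_nema_spec, nm_grid32):
        """Scaling all fills by a scales all estimates by a (noise-free)."""
        cfg = AcquisitionConfig(
            n_angles=24, det_pixels=(32, 32), noise=False, scatter_fraction=0.3, psf_sigma_mm=4.5
        )
        cf = CalibrationFactor(cfg.sensitivity_cps_per_MBq)
        estimates = []
        for scale in (1.0, 3.0):
            spheres = tuple(
                type(s)(s.diameter_mm, s.center_mm, scale * s.activity_mCi)
                for s in compact_nema_spec.spheres
            )
            spec = PhantomSpec(
                body_semi_axes_mm=compact_nema_spec.body_semi_axes_mm,
                body_length_mm=compact_nema_spec.body_length_mm,
                spheres=spheres,
            )
            act, mu = build_nema(spec, nm_grid32)
            proj = simulate_acquisition(act, mu, cfg)
            rec = mlem_reconstruct(tew_correct(proj), mu, cfg, iterations=8, subsets=4)
            rows = sphere_recovery(rec, nema_sphere_masks(spec, nm_grid32), cf, margin_mm=10.0)
            estimates.append(np.array([r.estimated_mCi for r in rows]))
        assert np.allclose(estimates[1], 3.0 * estimates[0], rtol=0.02)

    def test_overlapping_vois_rejected(self, nm_grid32):
        from spectdose.phantoms import SphereSpec

        spec = PhantomSpec(
            body_semi_axes_mm=(60.0, 60.0),
            body_length_mm=120.0,
            spheres=(
                SphereSpec(22.0, (-15.0, 0.0, 0.0), 0.1),
                SphereSpec(22.0, (15.0, 0.0, 0.0), 0.1),
            ),
        )
        contours = nema_sphere_masks(spec, nm_grid32)
        rec = nm_grid32.like(np.ones(nm_grid32.shape), "cps")
        with pytest.raises(ValueError, match="overlap"):
            sphere_recovery(rec, contours, CalibrationFactor(5.0), margin_mm=10.0)

    def test_empty_contours_empty_report(self, nm_grid16):
        rec = nm_grid16.like(np.ones(nm_grid16.shape), "cps")
        assert sphere_recovery(rec, [], CalibrationFactor(5.0)) == []

    def test_metric_dilation(self, nm_grid16):
        mask = nm_grid16.like(np.zeros(nm_grid16.shape, bool), "mask")
        mask.data[8, 8, 8] = True
        voi = dilate_mask_mm(mask, 10.0)
        # 10 mm at 4.42-mm voxels reaches the 2-voxel face neighbours (8.84)
        # but not 3 voxels out (13.26), nor the (2,2,0) diagonal (12.5)
        assert voi.data[10, 8, 8] and voi.data[8, 6, 8]
        assert not voi.data[11, 8, 8] and not voi.data[10, 10, 8]
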