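"""Tests for the NU-4 metrics, line profiles, widths and post-filter."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from petprc import metrics as M
from petprc.grid import VoxelGrid, centered_grid


def _vol(values):
    return VoxelGrid(np.asarray(values, dtype=float), (1, 1, 1), (0, 0, 0), "activity")


class TestPercentSD:
    def test_constant_roi_is_zero(self):
        v = _vol(np.full((4, 4, 4), 3.0))
        assert M.percent_sd(v, np.ones(v.shape, dtype=bool)) == 0.0

    def test_two_point_population_sd(self):
        # population SD of {1, 3} is 1, mean 2
        vals = np.zeros((2, 1, 1))
        vals[0, 0, 0], vals[1, 0, 0] = 1.0, 3.0
        assert M.percent_sd(_vol(vals), np.ones((2, 1, 1), bool)) == pytest.approx(0.5)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(1, 2, (5, 5, 5))
        roi = np.ones(vals.shape, bool)
        assert M.percent_sd(_vol(vals), roi) == pytest.approx(
            M.percent_sd(_vol(7.3 * vals), roi)
        )

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            M.percent_sd(_vol(np.zeros((3, 3, 3))), np.ones((3, 3, 3), bool))


class TestSpilloverRatio:
    def test_zero_cold_region(self):
        vals = np.ones((4, 4, 2))
        vals[:2] = 0.0
        cold = np.zeros(vals.shape, bool)
        cold[:2] = True
        ratio, sd = M.spillover_ratio(_vol(vals), cold, ~cold)
        assert ratio == 0.0 and sd == 0.0

    def test_direct_ratio(self):
        vals = np.ones((4, 4, 2)) * 2.0
        cold = np.zeros(vals.shape, bool)
        cold[:2] = True
        vals[cold] = 0.2
        ratio, _ = M.spillover_ratio(_vol(vals), cold, ~cold)
        assert ratio == pytest.approx(0.1)

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(0.5, 1.5, (6, 6, 2))
        cold = np.zeros(vals.shape, bool)
        cold[:3] = True
        r1, s1 = M.spillover_ratio(_vol(vals), cold, ~cold)
        r2, s2 = M.spillover_ratio(_vol(4.2 * vals), cold, ~cold)
        assert r1 == pytest.approx(r2) and s1 == pytest.approx(s2)


class TestRecoveryCoefficients:
    def test_identity_image_recovers_one(self):
        from petprc.phantoms import gen_nema_nu4

        activity, _, rois = gen_nema_nu4(0.5)
        rc = M.recovery_coefficients(activity, rois.rods, rois.rod_slices, rois.uniform)
        for d, (val, _) in rc.items():
            assert val == pytest.approx(1.0), f"rod {d} mm"

    def test_gaussian_blurred_rod_matches_closed_form(self):
        from scipy.ndimage import gaussian_filter

        # 3 mm rod blurred by an isotropic in-plane Gaussian: the central
        # (max) value is 1 - exp(-R^2 / 2 sigma^2)
        vs = 0.1
        sigma_mm = 1.2
        grid = centered_grid((180, 180, 12), vs)
        x, y, _ = np.meshgrid(*grid.world_axes(), indexing="ij", sparse=True)
        rod = np.broadcast_to(x**2 + y**2 <= 1.5**2, grid.shape).astype(float)
        blurred = gaussian_filter(rod, sigma_mm / vs)
        vol = grid.like(blurred)
        roi = np.broadcast_to(x**2 + y**2 <= 3.0**2, grid.shape)
        uniform = np.ones(grid.shape, bool)  # uniform mean via unit input
        rc = M.recovery_coefficients(
            grid.like(np.ones(grid.shape)), {3: roi}, (3, 9), uniform
        )
        assert rc[3][0] == pytest.approx(1.0)
        vals = np.where(roi[:, :, 3:9], blurred[:, :, 3:9], -np.inf)
        measured = vals.max(axis=(0, 1)).mean()
        expected = 1.0 - np.exp(-(1.5**2) / (2 * sigma_mm**2))
        assert measured == pytest.approx(expected, rel=0.02)

    def test_missing_rod_roi_rejected(self):
        v = _vol(np.ones((4, 4, 4)))
        with pytest.raises(ValueError):
            M.recovery_coefficients(
                v, {1: np.zeros((4, 4, 4), bool)}, (0, 4), np.ones((4, 4, 4), bool)
            )


class TestLineProfile:
    def test_constant_volume(self):
        grid = centered_grid((16, 16, 16), 1.0)
        vol = grid.like(np.full(grid.shape, 2.5))
        prof = M.line_profile(vol, (-5, 0, 0), (5, 0, 0), 0.25)
        assert np.allclose(prof.values, 2.5)

    def test_linear_ramp_reproduced_exactly(self):
        grid = centered_grid((16, 16, 16), 1.0)
        x, _, _ = np.meshgrid(*grid.world_axes(), indexing="ij", sparse=True)
        vol = grid.like(np.broadcast_to(3.0 + 0.5 * x, grid.shape).copy(), kind="value")
        prof = M.line_profile(vol, (-5, 1, 2), (5, 1, 2), 0.2)
        expected = 3.0 + 0.5 * (prof.positions - 5.0)
        assert np.allclose(prof.values, expected, atol=1e-9)

    def test_out_of_volume_endpoint_rejected(self):
        grid = centered_grid((8, 8, 8), 1.0)
        with pytest.raises(ValueError):
            M.line_profile(grid, (0, 0, 0), (100, 0, 0))

    def test_cylinder_profile_close_to_nearest_voxel_sampling(self):
        grid = centered_grid((32, 32, 8), 0.5)
        x, y, _ = np.meshgrid(*grid.world_axes(), indexing="ij", sparse=True)
        vol = grid.like(np.broadcast_to(x**2 + y**2 <= 4.0**2, grid.shape).astype(float))
        prof = M.line_profile(vol, (-7, 0, 0), (7, 0, 0), 0.05)
        # half-crossings of the interpolated profile within a voxel of the edge
        inside = prof.positions[prof.values > 0.5]
        assert abs((inside.min() - 7.0) - (-4.0)) <= 0.5
        assert abs((inside.max() - 7.0) - 4.0) <= 0.5


class TestWidths:
    def _gauss_profile(self, sigma=2.0, step=0.05):
        x = np.arange(-15, 15 + step, step)
        return M.LineProfile(x - x[0], np.exp(-(x**2) / (2 * sigma**2)))

    def test_gaussian_widths(self):
        prof = self._gauss_profile(sigma=2.0, step=0.05)
        fwhm, fwtm = M.fwhm_fwtm(prof)
        assert fwhm == pytest.approx(2.0 * 2.3548, abs=0.05)
        assert fwtm == pytest.approx(2.0 * 4.2919, abs=0.05)

    def test_triangle_half_width(self):
        x = np.arange(0, 20.0001, 0.1)
        y = np.maximum(1.0 - np.abs(x - 10.0) / 4.0, 0.0)
        fwhm, _ = M.fwhm_fwtm(M.LineProfile(x, y))
        assert fwhm == pytest.approx(4.0, abs=0.1)

    def test_fwtm_not_smaller_than_fwhm(self):
        prof = self._gauss_profile(sigma=1.3, step=0.1)
        fwhm, fwtm = M.fwhm_fwtm(prof)
        assert fwtm >= fwhm

    def test_error_when_profile_never_falls(self):
        x = np.arange(0, 10.1, 0.1)
        with pytest.raises(ValueError):
            M.fwhm_fwtm(M.LineProfile(x, np.ones_like(x)))

    def test_pedestal_subtraction(self):
        # peak of height 1 on a pedestal of 0.5: FWHM measured above pedestal
        x = np.arange(0, 20.0001, 0.02)
        y = 0.5 + np.exp(-((x - 10) ** 2) / (2 * 1.0**2))
        fwhm, _ = M.fwhm_fwtm(M.LineProfile(x, y))
        assert fwhm == pytest.approx(2.3548, abs=0.05)

    @settings(max_examples=25, deadline=None)
    @given(
        sigma=st.floats(0.8, 4.0),
        center=st.floats(8.0, 12.0),
        step=st.sampled_from([0.05, 0.1, 0.2]),
    )
    def test_matches_dense_resampling_oracle(self, sigma, center, step):
        x = np.arange(0.0, 20.0 + step, step)
        y = np.exp(-((x - center) ** 2) / (2 * sigma**2))
        fwhm, fwtm = M.fwhm_fwtm(M.LineProfile(x, y))
        # brute-force oracle: dense linear resampling with the same
        # flanking-minimum pedestal convention, threshold count
        xf = np.linspace(0, 20, 200001)
        yf = np.interp(xf, x, y)
        i_peak = int(np.argmax(yf))
        ped = 0.5 * (yf[:i_peak + 1].min() + yf[i_peak:].min())
        for width, frac in ((fwhm, 0.5), (fwtm, 0.1)):
            dense = xf[yf >= ped + frac * (yf.max() - ped)]
            assert width == pytest.approx(dense.max() - dense.min(), abs=step)


class TestButterworth:
    def test_constant_volume_unchanged(self):
        vol = _vol(np.full((16, 16, 16), 1.7))
        out = M.butterworth3d(vol)
        assert np.allclose(out.values, 1.7, atol=1e-9)

    def test_gain_at_cutoff_is_half_power(self):
        n = 64
        cutoff = 0.2
        grid = centered_grid((n, n, 4), 1.0)
        # pure cosine at exactly the cutoff frequency along x
        k = int(round(cutoff * 0.5 * n))  # cycles per n samples
        x = np.arange(n)
        wave = np.cos(2 * np.pi * k * x / n)
        vol = grid.like(np.broadcast_to(wave[:, None, None], grid.shape).copy(), kind="value")
        out = M.butterworth3d(vol, order=10, cutoff=2 * k / n)
        # measured attenuation of the wave amplitude
        gain = np.ptp(out.values) / np.ptp(vol.values)
        assert gain == pytest.approx(1 / np.sqrt(2), abs=0.02)

    def test_nyquist_checkerboard_strongly_attenuated(self):
        n = 16
        idx = np.indices((n, n, n)).sum(axis=0)
        checker = np.where(idx % 2 == 0, 1.0, -1.0)
        vol = VoxelGrid(checker, (1, 1, 1), (0, 0, 0), "value")
        out = M.butterworth3d(vol, order=10, cutoff=0.2)
        assert np.abs(out.values).max() < np.abs(checker).max() / 10

    def test_invalid_cutoff_rejected(self):
        with pytest.raises(ValueError):
            M.butterworth3d(_vol(np.ones((4, 4, 4))), cutoff=0.0)

    def test_passband_identity_on_bandlimited_input(self):
        rng = np.random.default_rng(5)
        vals = rng.uniform(size=(16, 16, 16))
        # band-limit periodically with a sharp low cutoff first
        smooth = M.butterworth3d(
            VoxelGrid(vals, (1, 1, 1), (0, 0, 0), "value"), order=20, cutoff=0.25
        )
        out = M.butterworth3d(smooth, order=40, cutoff=1.0)
        assert np.abs(out.values - smooth.values).max() < 1e-6


class TestSweep:
    def test_single_snapshot_single_report(self):
        from petprc.phantoms import gen_nema_nu4

        activity, _, rois = gen_nema_nu4(0.5)
        reports = M.nema_sweep([activity], rois, [40])
        assert len(reports) == 1 and reports[0].iteration == 40

    def test_reports_preserve_iteration_order(self):
        from petprc.phantoms import gen_nema_nu4

        activity, _, rois = gen_nema_nu4(0.5)
        reports = M.nema_sweep([activity, activity], rois, [10, 20])
        assert [r.iteration for r in reports] == [10, 20]
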