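"""Tests for segmentation, PRC blur operators and the OSEM core."""

import numpy as np
import pytest

from petprc import phantoms as P
from petprc import projection as PR
from petprc import recon as R
from petprc.grid import AIR_DENSITY, VoxelGrid, centered_grid
from petprc.kernels import build_uniform_kernel


class TestSegmentation:
    def test_levels_one_all_water(self):
        dens = centered_grid((8, 8, 8), 1.0, "density")
        dens.values[:] = 0.7
        seg = R.segment_density(dens, 1)
        assert np.all(seg.labels.values == 0)
        assert seg.table[0] == ("water", 1.0)

    def test_nema_levels_two(self):
        _, dens, _ = P.gen_nema_nu4(0.8)
        seg = R.segment_density(dens, 2)
        labs = np.unique(seg.labels.values)
        assert set(labs) == {0, 1}
        assert np.array_equal(seg.labels.values == 0, dens.values < 0.5)

    def test_rat_thorax_levels_three_matches_masks(self):
        _, dens = P.gen_rat_thorax(1.0)
        seg = R.segment_density(dens, 3)
        # ground-truth phantom tissues map exactly onto the classes
        assert np.array_equal(
            seg.labels.values == 2, dens.values == P.BONE
        )
        assert np.array_equal(
            seg.labels.values == 1, dens.values == P.WATER
        )
        lung_or_air = (dens.values == P.LUNG) | (dens.values == AIR_DENSITY)
        assert np.array_equal(seg.labels.values == 0, lung_or_air)

    def test_unsupported_levels_rejected(self):
        dens = centered_grid((4, 4, 4), 1.0, "density")
        with pytest.raises(ValueError):
            R.segment_density(dens, 4)


class TestPrcBlur:
    def test_delta_source_reproduces_water_kernel(self, rb82_params):
        shape = (31, 31, 31)
        img = centered_grid(shape, 1.0)
        img.values[15, 15, 15] = 1.0
        dens = img.like(np.ones(shape), kind="density")
        seg = R.segment_density(dens, 1)
        out = R.prc_blur(img, "td", seg, rb82_params, kernel_size=21)
        kern = build_uniform_kernel(rb82_params, 1.0, 21, 1.0)
        got = out.values[5:26, 5:26, 5:26]
        assert np.abs(got - kern.weights).max() < 1e-6

    def test_td_equals_tdsv_on_uniform_density(self, rb82_params):
        shape = (24, 24, 24)
        rng = np.random.default_rng(2)
        img = centered_grid(shape, 1.0)
        img.values[:] = rng.uniform(size=shape)
        dens = img.like(np.ones(shape), kind="density")
        seg = R.segment_density(dens, 1)
        td = R.prc_blur(img, "td", seg, rb82_params, kernel_size=13, density=dens)
        tdsv = R.prc_blur(img, "tdsv", seg, rb82_params, kernel_size=13, density=dens)
        assert np.abs(td.values - tdsv.values).max() < 1e-7 * img.values.max()

    def test_total_activity_conserved(self, rb82_params):
        shape = (26, 26, 26)
        img = centered_grid(shape, 1.0)
        img.values[10:16, 10:16, 10:16] = 2.0
        dens = img.like(np.full(shape, 0.5), kind="density")
        dens.values[13:, :, :] = 1.0
        seg = R.segment_density(dens, 2)
        for mode in ("td", "tdsv"):
            out = R.prc_blur(img, mode, seg, rb82_params, kernel_size=11, density=dens)
            assert out.values.sum() == pytest.approx(img.values.sum(), rel=1e-5)

    def test_grid_mismatch_rejected(self, rb82_params):
        img = centered_grid((8, 8, 8), 1.0)
        dens = centered_grid((10, 10, 10), 1.0, "density")
        dens.values[:] = 1.0
        seg = R.segment_density(dens, 1)
        with pytest.raises(ValueError):
            R.prc_blur(img, "td", seg, rb82_params)

    def test_variant_superposition_close_to_exact_across_boundary(self, rb82_params):
        from petprc.blur import ExactVariantBlur, VariantSuperpositionBlur

        shape = (18, 18, 18)
        dens = centered_grid(shape, 1.0, "density")
        dens.values[:] = 1.0
        dens.values[9:, :, :] = 0.3  # water | lung interface
        x = np.zeros(shape)
        x[8, 9, 9] = 1.0
        fast = VariantSuperpositionBlur(dens, rb82_params, kernel_size=9).apply(x)
        exact = ExactVariantBlur(dens, rb82_params, kernel_size=9).apply(x)
        # same mass, same asymmetry direction, strong voxelwise agreement
        assert fast.sum() == pytest.approx(exact.sum(), rel=1e-5)
        assert fast[9:, :, :].sum() > fast[:8, :, :].sum()
        assert exact[9:, :, :].sum() > exact[:8, :, :].sum()
        corr = np.corrcoef(fast.ravel(), exact.ravel())[0, 1]
        assert corr > 0.9


def _toy_system():
    grid = centered_grid((12, 12, 2), 1.0)
    rng = np.random.default_rng(7)
    grid.values[:] = rng.uniform(0.5, 2.0, grid.shape)
    geom = PR.ProjectionGeometry.for_grid(grid, n_angles=8)
    return grid, geom


class TestOsem:
    def test_single_iteration_matches_mlem_formula(self):
        grid, geom = _toy_system()
        sino = PR.forward_project(grid, geom)
        sino = PR.ProjectionData(sino.values, geom, PR.make_subsets(8, 1))
        cfg = R.ReconConfig(iterations=1, subsets=1, prc_mode="none")
        res = R.osem(sino, geom, cfg, dtype=np.float64)
        # brute-force MLEM oracle from the dense system matrix
        a = geom.system_matrix().toarray()
        nvox = grid.shape[0] * grid.shape[1]
        y = sino.values.reshape(-1, 2)
        x0 = np.ones((nvox, 2))
        sens = a.T @ np.ones((a.shape[0], 2))
        ax = a @ x0
        floor = max(ax.max() * 1e-8, 1e-20)
        ratio = y / np.maximum(ax, floor)
        x1 = np.where(sens > 1e-6 * sens.max(), x0 * (a.T @ ratio) / sens, 0.0)
        got = res.final.values.reshape(nvox, 2)
        mask = sens > 1e-6 * sens.max()
        assert np.abs(got[mask] - x1[mask]).max() < 1e-12

    def test_loglikelihood_monotone_one_subset(self):
        grid, geom = _toy_system()
        sino = PR.forward_project(grid, geom)  # noiseless data, matched model
        sino = PR.ProjectionData(sino.values, geom, PR.make_subsets(8, 1))
        cfg = R.ReconConfig(iterations=30, subsets=1, prc_mode="none")
        res = R.osem(sino, geom, cfg, compute_loglik=True, snapshot_iters=[30])
        ll = np.array(res.log_likelihood)
        assert np.all(np.diff(ll) > -1e-3 * np.abs(ll[0]))

    def test_postfilter_applied_to_snapshots(self):
        grid, geom = _toy_system()
        sino = PR.forward_project(grid, geom)
        sino = PR.ProjectionData(sino.values, geom, PR.make_subsets(8, 1))
        plain = R.osem(sino, geom, R.ReconConfig(iterations=3, subsets=1))
        filt = R.osem(
            sino, geom,
            R.ReconConfig(iterations=3, subsets=1, postfilter=(10, 0.2)),
        )
        # low-pass filtering shrinks the high-frequency content
        d_plain = np.abs(np.diff(plain.final.values, axis=0)).mean()
        d_filt = np.abs(np.diff(filt.final.values, axis=0)).mean()
        assert d_filt < d_plain

    def test_zero_sinogram_gives_zero_image(self):
        grid, geom = _toy_system()
        sino = PR.ProjectionData(np.zeros(geom.sino_shape), geom, PR.make_subsets(8, 1))
        res = R.osem(sino, geom, R.ReconConfig(iterations=1, subsets=1))
        assert np.all(res.final.values == 0)

    def test_subsets_must_divide_angles(self):
        grid, geom = _toy_system()
        sino = PR.forward_project(grid, geom)
        sino.subsets = [np.arange(5), np.arange(5, 8)]
        with pytest.raises(ValueError):
            R.osem(sino, geom, R.ReconConfig(iterations=1, subsets=2))

    def test_noiseless_recovery_small_inverse_crime(self):
        # matched blur-free system: OSEM should approach the true image
        grid = centered_grid((12, 12, 2), 1.0)
        rng = np.random.default_rng(7)
        grid.values[:] = rng.uniform(0.5, 2.0, grid.shape)
        geom = PR.ProjectionGeometry.for_grid(grid, n_angles=24)
        sino = PR.forward_project(grid, geom)
        sino = PR.ProjectionData(sino.values, geom, PR.make_subsets(24, 4))
        res = R.osem(sino, geom, R.ReconConfig(iterations=60, subsets=4), snapshot_iters=[60])
        err = np.abs(res.final.values - grid.values) / grid.values.max()
        assert np.median(err) < 0.05


class TestInverseCrimeRecovery:
    def test_matched_range_model_recovers_wall_width(self, rb82_params):
        """Noiseless data with uniform-water blur: TD 1 drives the wall
        width to the true 3 mm (plus voxel quantization); no-PRC does not."""
        from petprc import metrics as M
        from petprc import phantoms as P

        act, dens, _ = P.gen_cardiac(0.5, shape=(64, 64, 28))
        geom = PR.ProjectionGeometry.for_grid(act, n_angles=48)
        sino = PR.simulate_acquisition(
            act, dens, rb82_params, "uniform", geom, 1e7, seed=0,
            detector_fwhm_mm=0.0, kernel_size=41, noiseless=True,
        )
        att = PR.attenuation_factors(dens, geom)
        seg = R.segment_density(dens, 1)
        widths = {}
        for key, cfg in (
            ("none", R.ReconConfig(iterations=48, subsets=16, prc_mode="none")),
            ("td1", R.ReconConfig(iterations=48, subsets=16, prc_mode="td",
                                  td_levels=1, td_kernel_size=41)),
        ):
            res = R.osem(sino, geom, cfg, seg=seg, params=rb82_params,
                         density=dens, attenuation=att, snapshot_iters=[48])
            prof = M.radial_wall_profile(
                res.final, r_max=14.5, z_offsets_mm=(-2.0, 0.0, 2.0)
            )
            widths[key] = M.fwhm_fwtm(
                prof, peak_region=(7.5, 12.5), search_region=(0.0, 14.4),
                fractions=(0.5,),
            )[0]
        assert widths["td1"] <= 3.0 + 2 * 0.5
        assert widths["none"] > widths["td1"]


class TestReconConfig:
    def test_name_reflects_mode(self):
        assert R.ReconConfig(prc_mode="none").name == "no PRC"
        assert R.ReconConfig(prc_mode="td", td_levels=2).name == "TD 2"
        assert R.ReconConfig(prc_mode="tdsv", tdsv_kernel_size=41).name == "TDSV 41"

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            R.ReconConfig(iterations=0)
        with pytest.raises(ValueError):
            R.ReconConfig(prc_mode="bogus")
        with pytest.raises(ValueError):
            R.ReconConfig(tdsv_kernel_size=20, prc_mode="tdsv")
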