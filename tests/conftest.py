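"""Shared fixtures.

The end-to-end simulation + reconstruction studies (NEMA NU-4, cardiac,
gated thorax) are session-scoped so the acceptance checks and the
qualitative reconstruction tests share single runs.  Problem sizes are
reduced relative to a production scan (smaller grids, fewer angles) but
keep the physics conditions: 0.4-0.5 mm voxels, 1.6 mm detector blur,
40 iterations / 16 subsets, spatially variant range blur in the ground
truth.
"""

import numpy as np
import pytest

from petprc import gating as G
from petprc import kernels as K
from petprc import metrics as M
from petprc import phantoms as P
from petprc import projection as PR
from petprc import recon as R


@pytest.fixture(scope="session")
def rb82_params():
    """Fitted 82Rb water kernel from a reduced Monte Carlo reference."""
    return K.rb82_water_params(n_decays=200_000, seed=20220730)


@pytest.fixture(scope="session")
def cardiac_run(rb82_params):
    """Cardiac phantom: simulate once, reconstruct without PRC and with TDSV 41."""
    act, dens, landmarks = P.gen_cardiac(0.4, shape=(96, 96, 48))
    geom = PR.ProjectionGeometry.for_grid(act, n_angles=96)
    sino = PR.simulate_acquisition(
        act, dens, rb82_params, "variant", geom, 6e6, seed=42,
        detector_fwhm_mm=1.6,
    )
    att = PR.attenuation_factors(dens, geom)
    seg = R.segment_density(dens, 2)
    vols = {}
    for key, cfg in (
        ("none", R.ReconConfig(iterations=40, subsets=16, prc_mode="none")),
        ("tdsv41", R.ReconConfig(iterations=40, subsets=16, prc_mode="tdsv",
                                 tdsv_kernel_size=41)),
    ):
        res = R.osem(sino, geom, cfg, seg=seg, params=rb82_params, density=dens,
                     attenuation=att, snapshot_iters=[40])
        vols[key] = res.final
    return {"activity": act, "density": dens, "landmarks": landmarks, "vols": vols}


def cardiac_wall_widths(vol, fractions=(0.5, 0.1)):
    """FWHM (and FWTM) of the lateral LV wall on the averaged radial profile."""
    prof = M.radial_wall_profile(vol, r_max=17.0)
    return M.fwhm_fwtm(
        prof, peak_region=(7.5, 12.5), search_region=(0.0, 16.9), fractions=fractions
    )


@pytest.fixture(scope="session")
def nema_run(rb82_params):
    """NEMA NU-4: simulate once, reconstruct with no PRC, TD 2 and TDSV 41."""
    act, dens, rois = P.gen_nema_nu4(0.5, shape=(68, 68, 104))
    geom = PR.ProjectionGeometry.for_grid(act, n_angles=64)
    sino = PR.simulate_acquisition(
        act, dens, rb82_params, "variant", geom, 4e9, seed=99,
        detector_fwhm_mm=1.6,
    )
    att = PR.attenuation_factors(dens, geom)
    seg = R.segment_density(dens, 2)
    out = {"rois": rois, "density": dens, "reports": {}, "vols": {}, "sweeps": {}}
    for key, cfg in (
        ("none", R.ReconConfig(iterations=40, subsets=16, prc_mode="none")),
        ("td2", R.ReconConfig(iterations=40, subsets=16, prc_mode="td", td_levels=2)),
        ("tdsv41", R.ReconConfig(iterations=40, subsets=16, prc_mode="tdsv",
                                 tdsv_kernel_size=41)),
    ):
        res = R.osem(sino, geom, cfg, seg=seg, params=rb82_params, density=dens,
                     attenuation=att, snapshot_iters=[20, 40])
        out["vols"][key] = res.final
        out["sweeps"][key] = M.nema_sweep(res.images, rois, res.iterations)
        out["reports"][key] = out["sweeps"][key][-1]
    return out


def _thorax_factory(voxel_size, shape, amplitude_mm):
    def factory(phase):
        return P.gen_rat_thorax(
            voxel_size, phase=phase, shape=shape, amplitude_mm=amplitude_mm
        )

    return factory


@pytest.fixture(scope="session")
def gated_static_run(rb82_params):
    """Motionless thorax: 4-bin gated sum vs ungated reconstruction."""
    shape = (38, 34, 36)
    factory = _thorax_factory(1.0, shape, amplitude_mm=0.0)
    act, dens = factory(0.0)
    geom = PR.ProjectionGeometry.for_grid(act, n_angles=48)
    counts = 1e7
    cfg = R.ReconConfig(iterations=10, subsets=16, prc_mode="td", td_levels=1,
                        td_kernel_size=21)
    scheme = G.simulate_gated(
        factory, 4, geom, rb82_params, counts, seed=7,
        prc_truth_mode="variant", kernel_size=21,
    )
    gated_sum, _ = G.reconstruct_gated(scheme, geom, cfg, params=rb82_params)
    # ungated acquisition: all events in one histogram
    ungated = PR.simulate_acquisition(
        act, dens, rb82_params, "variant", geom, counts, seed=8, kernel_size=21,
    )
    att = PR.attenuation_factors(dens, geom)
    seg = R.segment_density(dens, 1)
    res = R.osem(ungated, geom, cfg, seg=seg, params=rb82_params, density=dens,
                 attenuation=att, snapshot_iters=[cfg.iterations])
    return {"gated_sum": gated_sum, "ungated": res.final, "activity": act}


@pytest.fixture(scope="session")
def gated_moving_run(rb82_params):
    """Breathing thorax: gated (4 bins) vs ungated reconstruction, TD 1."""
    shape = (38, 34, 36)
    factory = _thorax_factory(1.0, shape, amplitude_mm=2.0)
    geom = PR.ProjectionGeometry.for_grid(factory(0.0)[0], n_angles=48)
    counts = 8e6
    cfg = R.ReconConfig(iterations=40, subsets=16, prc_mode="td", td_levels=1,
                        td_kernel_size=21)
    scheme = G.simulate_gated(
        factory, 4, geom, rb82_params, counts, seed=17,
        prc_truth_mode="variant", kernel_size=21,
    )
    gated_sum, per_bin = G.reconstruct_gated(scheme, geom, cfg, params=rb82_params)
    # ungated data: pool the gated bins (same events, no phase separation)
    pooled = PR.ProjectionData(
        np.sum([b.values for b in scheme.bins], axis=0), geom, scheme.bins[0].subsets
    )
    act0, dens0 = factory(0.0)
    att = PR.attenuation_factors(dens0, geom)
    seg = R.segment_density(dens0, 1)
    res = R.osem(pooled, geom, cfg, seg=seg, params=rb82_params, density=dens0,
                 attenuation=att, snapshot_iters=[cfg.iterations])
    return {"gated_sum": gated_sum, "per_bin": per_bin, "ungated": res.final}


def apex_wall_fwhm(vol):
    """FWHM of the apical myocardial wall along the motion (z) axis.

    Averages profiles over a small transaxial disc around the heart axis
    to suppress reconstruction speckle.
    """
    profs = []
    for dx in (-1.0, 0.0, 1.0):
        for dy in (-1.0, 0.0, 1.0):
            prof = M.line_profile(
                vol, (dx, 3.0 + dy, -16.0), (dx, 3.0 + dy, 16.0), 0.1
            )
            profs.append(prof.values)
    avg = M.LineProfile(prof.positions, np.mean(profs, axis=0))
    # apical wall sits near z = -8 (positions ~ 8 mm from the line start)
    fwhm, _ = M.fwhm_fwtm(avg, peak_region=(4.0, 12.0), search_region=(0.0, 16.0))
    return fwhm
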