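"""Respiratory gating: phase-binned simulation, per-bin reconstruction,
and summation into a single static image.

Equal-width phase bins with midpoint representative phases; each bin's
acquisition is simulated with the phantom frozen at that phase
(quasi-static approximation) and 1/n_bins of the total expected counts,
so the count partition is exact.  Per-bin reconstructions share one
configuration and are summed voxelwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import VoxelGrid
from .kernels import APSFParams
from .projection import ProjectionData, ProjectionGeometry, attenuation_factors, simulate_acquisition
from .recon import ReconConfig, TissueSegmentation, osem, segment_density


@dataclass
class GatingScheme:
    """Phase-binned projection data with per-bin phantom state."""

    n_bins: int
    edges: np.ndarray  # bin edges on [0, 1]
    phases: np.ndarray  # representative (midpoint) phase per bin
    bins: list[ProjectionData] = field(default_factory=list)
    densities: list[VoxelGrid] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")
        if len(self.edges) != self.n_bins + 1 or self.edges[0] != 0.0 or self.edges[-1] != 1.0:
            raise ValueError("edges must partition [0, 1)")


def bin_phases(n_bins: int) -> tuple[np.ndarray, np.ndarray]:
    """Equal-width bin edges and midpoint representative phases."""
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    return edges, 0.5 * (edges[:-1] + edges[1:])


def simulate_gated(
    phantom_at_phase,
    n_bins: int,
    geom: ProjectionGeometry,
    params: APSFParams,
    total_counts: float,
    seed: int,
    prc_truth_mode: str = "variant",
    **sim_kwargs,
) -> GatingScheme:
    """Simulate one acquisition per respiratory bin.

    ``phantom_at_phase(phase) -> (activity, density)`` instantiates the
    moving phantom; each bin receives ``total_counts / n_bins`` expected
    events with an independent child seed derived from ``seed``.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    edges, phases = bin_phases(n_bins)
    scheme = GatingScheme(n_bins, edges, phases)
    children = np.random.SeedSequence(seed).spawn(n_bins)
    for b, phase in enumerate(phases):
        activity, density = phantom_at_phase(float(phase))
        proj = simulate_acquisition(
            activity,
            density,
            params,
            prc_truth_mode,
            geom,
            total_counts / n_bins,
            seed=int(children[b].generate_state(1)[0] % (2**31)),
            **sim_kwargs,
        )
        scheme.bins.append(proj)
        scheme.densities.append(density)
    return scheme


def reconstruct_gated(
    scheme: GatingScheme,
    geom: ProjectionGeometry,
    config: ReconConfig,
    params: APSFParams | None = None,
    td_levels: int | None = None,
    attenuation: bool = True,
) -> tuple[VoxelGrid, list[VoxelGrid]]:
    """Reconstruct each bin independently and sum into a static image.

    Segmentation and attenuation are taken from each bin's own density
    (the CT follows the bin in a real gated protocol).  Returns the
    voxelwise sum and the per-bin volumes.
    """
    per_bin = []
    for proj, density in zip(scheme.bins, scheme.densities):
        seg: TissueSegmentation | None = None
        if config.prc_mode != "none":
            seg = segment_density(density, td_levels or config.td_levels)
        att = attenuation_factors(density, geom) if attenuation else None
        res = osem(
            proj,
            geom,
            config,
            seg=seg,
            params=params,
            density=density,
            attenuation=att,
            snapshot_iters=[config.iterations],
        )
        per_bin.append(res.final)
    total = per_bin[0].like(np.sum([v.values for v in per_bin], axis=0))
    return total, per_bin
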