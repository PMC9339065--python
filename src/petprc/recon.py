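"""3D-OSEM reconstruction with optional positron-range correction.

The system operator is ``y = att * P(B x)`` with ``P`` the stacked-2D
parallel-beam projector and ``B`` the positron-range blur: identity
(no PRC), tissue-dependent kernels on a CT-surrogate segmentation (TD),
or the spatially variant superposition operator (TDSV).  The adjoint uses
the exact transpose of the blur, so the projector pair is matched.

Updates follow the standard multiplicative OSEM scheme over
angle-interleaved subsets processed in bit-reversed order; the iteration
count is the stopping rule (no convergence test), matching the 1-100
iteration sweeps used for evaluation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .blur import (
    ExactVariantBlur,
    IdentityBlur,
    TissueKernelBlur,
    VariantSuperpositionBlur,
)
from .grid import AIR_DENSITY, VoxelGrid
from .kernels import APSFParams, build_uniform_kernel
from .projection import ProjectionData, ProjectionGeometry, bit_reversed_order

log = logging.getLogger(__name__)

#: Nominal densities (g/cm^3) of the segmentation classes.
CLASS_DENSITIES = {"air": AIR_DENSITY, "lung": 0.3, "water": 1.0, "bone": 1.9}


@dataclass
class TissueSegmentation:
    """Integer label volume plus a label -> (name, density) table."""

    labels: VoxelGrid
    table: dict[int, tuple[str, float]]

    def __post_init__(self) -> None:
        present = np.unique(self.labels.values)
        for lab in present:
            if int(lab) not in self.table:
                raise ValueError(f"label {lab} missing from table")
        for _, (_, rho) in self.table.items():
            if rho <= 0:
                raise ValueError("class densities must be positive")

    def mask(self, label: int) -> np.ndarray:
        return self.labels.values == label


def segment_density(density: VoxelGrid, levels: int) -> TissueSegmentation:
    """CT-surrogate segmentation of a density map into tissue classes.

    * levels=1: everything is water (homogeneous correction).
    * levels=2: threshold 0.5 g/cm^3 into {air, water}.
    * levels=3: thresholds {0.15 unused-below -> lung, 0.6, 1.4} into
      {lung, water, bone}; voxels below 0.15 (air) are assigned lung,
      since air outside the subject is masked by sensitivity anyway.
    """
    d = density.values
    lab = np.zeros(density.shape, dtype=np.int16)
    if levels == 1:
        table = {0: ("water", CLASS_DENSITIES["water"])}
    elif levels == 2:
        lab[d >= 0.5] = 1
        table = {0: ("air", CLASS_DENSITIES["air"]), 1: ("water", CLASS_DENSITIES["water"])}
    elif levels == 3:
        lab[(d >= 0.6) & (d < 1.4)] = 1
        lab[d >= 1.4] = 2
        table = {
            0: ("lung", CLASS_DENSITIES["lung"]),
            1: ("water", CLASS_DENSITIES["water"]),
            2: ("bone", CLASS_DENSITIES["bone"]),
        }
    else:
        raise ValueError(f"unsupported segmentation level count {levels}")
    return TissueSegmentation(density.like(lab, kind="label"), table)


@dataclass
class ReconConfig:
    """OSEM + PRC settings.

    ``prc_mode`` is one of ``"none"``, ``"td"`` (named by segmentation
    level count, e.g. TD 2) or ``"tdsv"`` (named by kernel size, e.g.
    TDSV 41).
    """

    iterations: int = 40
    subsets: int = 16
    prc_mode: str = "none"
    td_levels: int = 1
    tdsv_kernel_size: int = 41
    td_kernel_size: int = 41
    postfilter: tuple[float, float] | None = None  # (order, cutoff)
    floor: float = 0.0
    tdsv_exact: bool = False

    def __post_init__(self) -> None:
        if not 1 <= self.iterations <= 1000:
            raise ValueError("iterations must be in [1, 1000]")
        if self.prc_mode not in ("none", "td", "tdsv"):
            raise ValueError(f"unknown prc_mode {self.prc_mode!r}")
        if self.td_levels not in (1, 2, 3):
            raise ValueError("td_levels must be 1, 2 or 3")
        for size in (self.tdsv_kernel_size, self.td_kernel_size):
            if size % 2 == 0:
                raise ValueError("kernel sizes must be odd")

    @property
    def name(self) -> str:
        if self.prc_mode == "none":
            return "no PRC"
        if self.prc_mode == "td":
            return f"TD {self.td_levels}"
        return f"TDSV {self.tdsv_kernel_size}"


def make_prc_operator(
    config: ReconConfig,
    seg: TissueSegmentation | None,
    params: APSFParams | None,
    density: VoxelGrid | None,
    shape,
    voxel_size: float,
    dtype=np.float32,
):
    """Build the range-blur operator for the configured PRC mode."""
    if config.prc_mode == "none":
        return IdentityBlur()
    if params is None:
        raise ValueError("PRC requires fitted aPSF parameters")
    if config.prc_mode == "td":
        if seg is None:
            raise ValueError("TD correction requires a tissue segmentation")
        masks, kernels = [], []
        for label, (_, rho) in sorted(seg.table.items()):
            m = seg.mask(label)
            if not np.any(m):
                continue
            masks.append(m)
            kernels.append(build_uniform_kernel(params, rho, config.td_kernel_size, voxel_size))
        return TissueKernelBlur(shape, masks, kernels, dtype=dtype)
    if density is None:
        raise ValueError("TDSV correction requires the density grid")
    if config.tdsv_exact:
        return ExactVariantBlur(density, params, config.tdsv_kernel_size)
    return VariantSuperpositionBlur(density, params, config.tdsv_kernel_size, dtype=dtype)


def prc_blur(
    image: VoxelGrid,
    mode: str,
    seg: TissueSegmentation | None,
    params: APSFParams | None,
    kernel_size: int = 41,
    density: VoxelGrid | None = None,
) -> VoxelGrid:
    """Apply the positron-range blur of the given PRC mode to an image."""
    if seg is not None and not image.same_geometry(seg.labels):
        raise ValueError("image and segmentation grids do not match")
    if density is not None and not image.same_geometry(density):
        raise ValueError("image and density grids do not match")
    cfg = ReconConfig(
        prc_mode=mode if mode != "none" else "none",
        td_kernel_size=kernel_size,
        tdsv_kernel_size=kernel_size,
    )
    op = make_prc_operator(
        cfg, seg, params, density, image.shape, image.voxel_size[0], dtype=np.float64
    )
    out = np.maximum(np.asarray(op.apply(image.values), dtype=float), 0.0)
    return image.like(out)


@dataclass
class OsemResult:
    """Per-iteration snapshots of an OSEM run."""

    images: list[VoxelGrid] = field(default_factory=list)
    iterations: list[int] = field(default_factory=list)
    log_likelihood: list[float] = field(default_factory=list)

    @property
    def final(self) -> VoxelGrid:
        return self.images[-1]

    def at(self, iteration: int) -> VoxelGrid:
        return self.images[self.iterations.index(iteration)]


def osem(
    proj: ProjectionData,
    geom: ProjectionGeometry,
    config: ReconConfig,
    seg: TissueSegmentation | None = None,
    params: APSFParams | None = None,
    density: VoxelGrid | None = None,
    attenuation: np.ndarray | None = None,
    snapshot_every: int = 1,
    snapshot_iters=None,
    compute_loglik: bool = False,
    dtype=np.float32,
) -> OsemResult:
    """Ordered-subset EM reconstruction.

    Returns snapshots at the requested iterations (default: every
    iteration).  With one subset this is exact MLEM and the Poisson
    log-likelihood is non-decreasing.
    """
    nx, ny, nz = geom.image_shape
    vs = geom.voxel_size
    subsets = proj.subsets
    if geom.n_angles % len(subsets) != 0 or len({len(s) for s in subsets}) != 1:
        raise ValueError("subsets must evenly partition the angle count")
    dtype = np.dtype(dtype)
    blur = make_prc_operator(config, seg, params, density, (nx, ny, nz), vs, dtype=dtype)

    a32 = geom.system_matrix(dtype)
    rows = [
        np.concatenate([np.arange(ia * geom.n_radial, (ia + 1) * geom.n_radial) for ia in sub])
        for sub in subsets
    ]
    mats = [a32[r] for r in rows]

    y = proj.values.astype(dtype).reshape(geom.n_angles * geom.n_radial, nz)
    if attenuation is None:
        att = np.ones_like(y)
    else:
        att = attenuation.astype(dtype).reshape(geom.n_angles * geom.n_radial, nz)

    # per-subset sensitivity: B^T P_s^T att
    sens, masks = [], []
    for s, mat in enumerate(mats):
        bp = (mat.T @ att[rows[s]]).reshape(nx, ny, nz)
        sv = np.asarray(blur.adjoint(bp), dtype=dtype)
        m = sv > 1e-6 * sv.max() if sv.max() > 0 else np.zeros_like(sv, dtype=bool)
        if not np.all(m):
            log.info("subset %d: %d voxels outside sensitivity support", s, int((~m).sum()))
        sens.append(np.where(m, sv, 1.0))
        masks.append(m)

    order = bit_reversed_order(len(subsets))
    x = np.ones((nx, ny, nz), dtype=dtype)
    tiny = dtype.type(1e-20)
    result = OsemResult()
    snap_set = set(snapshot_iters) if snapshot_iters is not None else None

    origin = tuple(-(s - 1) / 2.0 * vs for s in (nx, ny, nz))
    for it in range(1, config.iterations + 1):
        for s in order:
            mat = mats[s]
            xb = np.asarray(blur.apply(x), dtype=dtype).reshape(nx * ny, nz)
            yhat = att[rows[s]] * (mat @ xb)
            # floor relative to the sinogram scale: bins with (near-)zero
            # model support but stray counts must not overflow float32
            floor = max(float(yhat.max()) * dtype.type(1e-8), tiny)
            ratio = y[rows[s]] / np.maximum(yhat, floor)
            upd = (mat.T @ (att[rows[s]] * ratio)).reshape(nx, ny, nz)
            upd = np.maximum(np.asarray(blur.adjoint(upd), dtype=dtype), 0.0)
            x = np.where(masks[s], x * upd / sens[s], 0.0)
            if config.floor:
                x = np.maximum(x, config.floor)
        if compute_loglik:
            xb = np.asarray(blur.apply(x), dtype=dtype).reshape(nx * ny, nz)
            yhat = att * (a32 @ xb)
            with np.errstate(divide="ignore", invalid="ignore"):
                ll = np.where(y > 0, y * np.log(np.maximum(yhat, tiny)), 0.0) - yhat
            result.log_likelihood.append(float(ll.sum()))
            log.info("iteration %d log-likelihood %.6g", it, result.log_likelihood[-1])
        take = (snap_set is not None and it in snap_set) or (
            snap_set is None and (it % snapshot_every == 0 or it == config.iterations)
        )
        if take:
            snap = VoxelGrid(x.astype(np.float64), (vs, vs, vs), origin, "activity")
            if config.postfilter is not None:
                from .metrics import butterworth3d

                bw_order, bw_cutoff = config.postfilter
                snap = butterworth3d(snap, order=bw_order, cutoff=bw_cutoff)
            result.images.append(snap)
            result.iterations.append(it)
    return result
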