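"""Stacked-2D parallel-beam projection and acquisition simulation.

The projector is a per-slice sparse matrix built with a pixel-driven
scheme: each voxel's mass is deposited on the two nearest radial bins by
linear interpolation with weight ``voxel_area / radial_spacing``, giving
line integrals in mm.  Forward and back projection share one matrix, so
the pair is an exact adjoint by construction.

The acquisition simulator applies positron-range blur in image space
(decay -> annihilation), forward projects the annihilation-site image,
attenuates, adds optional detector resolution blur in projection space,
scales to the requested expected count total and draws Poisson counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.ndimage import gaussian_filter1d

from .blur import ConvolutionBlur, IdentityBlur, VariantSuperpositionBlur
from .grid import VoxelGrid
from .kernels import APSFParams, build_uniform_kernel

#: Narrow-beam linear attenuation coefficient of water at 511 keV, 1/mm.
MU_WATER_511 = 0.0096

GAUSS_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))


def bit_reversed_order(n: int) -> list[int]:
    """Bit-reversal permutation of range(n), padded up to a power of two."""
    bits = max(1, int(np.ceil(np.log2(max(n, 1)))))
    order = []
    for i in range(2**bits):
        rev = int(format(i, f"0{bits}b")[::-1], 2)
        if rev < n:
            order.append(rev)
    return order


def make_subsets(n_angles: int, n_subsets: int) -> list[np.ndarray]:
    """Angle-interleaved subsets (subset k holds angles k, k+S, ...)."""
    if n_angles % n_subsets != 0:
        raise ValueError(f"{n_subsets} subsets do not divide {n_angles} angles")
    return [np.arange(k, n_angles, n_subsets) for k in range(n_subsets)]


@dataclass
class ProjectionGeometry:
    """Parallel-beam geometry tied to a reconstruction grid.

    ``angles`` span [0, pi); radial bins are centered on the grid center
    with ``radial_spacing`` mm pitch; slices stack along the image z axis.
    """

    angles: np.ndarray
    n_radial: int
    radial_spacing: float
    image_shape: tuple[int, int, int]
    voxel_size: float
    _matrices: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        if np.any(np.diff(self.angles) <= 0):
            raise ValueError("angles must be strictly increasing")
        if self.radial_spacing <= 0:
            raise ValueError("radial_spacing must be positive")

    @property
    def n_angles(self) -> int:
        return len(self.angles)

    @property
    def n_slices(self) -> int:
        return self.image_shape[2]

    @property
    def sino_shape(self) -> tuple[int, int, int]:
        return (self.n_angles, self.n_radial, self.n_slices)

    @classmethod
    def for_grid(cls, grid: VoxelGrid, n_angles: int = 96) -> "ProjectionGeometry":
        vs = grid.voxel_size
        if abs(vs[0] - vs[1]) > 1e-9:
            raise ValueError("in-plane voxels must be square")
        nx, ny, nz = grid.shape
        n_radial = int(np.ceil(np.hypot(nx, ny))) + 3
        angles = np.arange(n_angles) * np.pi / n_angles
        return cls(angles, n_radial, vs[0], (nx, ny, nz), vs[0])

    def system_matrix(self, dtype=np.float64) -> sp.csr_matrix:
        """Per-slice projection matrix, (n_angles*n_radial, nx*ny)."""
        key = np.dtype(dtype).name
        if key in self._matrices:
            return self._matrices[key]
        nx, ny, _ = self.image_shape
        vs = self.voxel_size
        cx = (nx - 1) / 2.0
        cy = (ny - 1) / 2.0
        xs = (np.arange(nx) - cx) * vs
        ys = (np.arange(ny) - cy) * vs
        x, y = np.meshgrid(xs, ys, indexing="ij")
        # 2x2 subpixel sampling suppresses the angle-dependent aliasing of
        # the plain pixel-driven scheme
        sub = (np.array([-0.25, 0.25]) * vs).tolist()
        cols = np.arange(nx * ny)
        rows_all, cols_all, vals_all = [], [], []
        s_center = (self.n_radial - 1) / 2.0
        w0 = vs * vs / self.radial_spacing / 4.0  # mm of path per deposit
        for ia, th in enumerate(self.angles):
            for dx in sub:
                for dy in sub:
                    s = (x + dx) * np.cos(th) + (y + dy) * np.sin(th)
                    t = s.ravel() / self.radial_spacing + s_center
                    i0 = np.floor(t).astype(int)
                    frac = t - i0
                    for i_bin, wt in ((i0, 1.0 - frac), (i0 + 1, frac)):
                        ok = (i_bin >= 0) & (i_bin < self.n_radial) & (wt > 0)
                        rows_all.append(ia * self.n_radial + i_bin[ok])
                        cols_all.append(cols[ok])
                        vals_all.append(w0 * wt[ok])
        mat = sp.csr_matrix(
            (
                np.concatenate(vals_all).astype(dtype),
                (np.concatenate(rows_all), np.concatenate(cols_all)),
            ),
            shape=(self.n_angles * self.n_radial, nx * ny),
        )
        self._matrices[key] = mat
        return mat


@dataclass
class ProjectionData:
    """Sinogram stack with its geometry and subset partition."""

    values: np.ndarray  # (n_angles, n_radial, n_slices)
    geometry: ProjectionGeometry
    subsets: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != self.geometry.sino_shape:
            raise ValueError(
                f"sinogram shape {self.values.shape} does not match geometry "
                f"{self.geometry.sino_shape}"
            )
        if np.any(self.values < 0):
            raise ValueError("projection values must be non-negative")
        if not self.subsets:
            n = self.geometry.n_angles
            n_sub = 16 if n % 16 == 0 else 1
            self.subsets = make_subsets(n, n_sub)
        cover = np.sort(np.concatenate(self.subsets))
        if not np.array_equal(cover, np.arange(self.geometry.n_angles)):
            raise ValueError("subsets must disjointly cover all angles")


def _check_grid(image: VoxelGrid, geom: ProjectionGeometry) -> None:
    if tuple(image.shape) != tuple(geom.image_shape):
        raise ValueError(f"image shape {image.shape} does not match geometry {geom.image_shape}")
    if abs(image.voxel_size[0] - geom.voxel_size) > 1e-9:
        raise ValueError("image voxel size does not match geometry")


def forward_project(image: VoxelGrid, geom: ProjectionGeometry) -> ProjectionData:
    """Line integrals (mm-weighted) of the image along every geometry ray."""
    _check_grid(image, geom)
    a = geom.system_matrix(image.values.dtype if image.values.dtype == np.float32 else np.float64)
    nx, ny, nz = geom.image_shape
    sino = a @ image.values.reshape(nx * ny, nz)
    return ProjectionData(sino.reshape(geom.sino_shape), geom)


def back_project(proj: ProjectionData, geom: ProjectionGeometry) -> VoxelGrid:
    """Exact adjoint of :func:`forward_project`."""
    if proj.values.shape != geom.sino_shape:
        raise ValueError("projection data does not match geometry")
    a = geom.system_matrix(proj.values.dtype if proj.values.dtype == np.float32 else np.float64)
    nx, ny, nz = geom.image_shape
    img = a.T @ proj.values.reshape(geom.n_angles * geom.n_radial, nz)
    vs = geom.voxel_size
    vals = img.reshape(nx, ny, nz)
    origin = tuple(-(s - 1) / 2.0 * vs for s in (nx, ny)) + (0.0,)
    # a raw adjoint, not an image estimate: values may carry any sign
    return VoxelGrid(vals, (vs, vs, vs), origin, "value")


def attenuation_factors(
    density: VoxelGrid, geom: ProjectionGeometry, mu_water: float = MU_WATER_511
) -> np.ndarray:
    """Multiplicative survival factors exp(-mu_water * int rho dl) per bin."""
    if np.any(density.values < 0):
        raise ValueError("density must be non-negative")
    _check_grid(density, geom)
    a = geom.system_matrix()
    nx, ny, nz = geom.image_shape
    path = (a @ density.values.reshape(nx * ny, nz)).reshape(geom.sino_shape)
    return np.exp(-mu_water * path)


def apply_detector_blur(sino: np.ndarray, geom: ProjectionGeometry, fwhm_mm: float) -> np.ndarray:
    """Isotropic Gaussian detector-resolution blur in projection space."""
    if fwhm_mm <= 0:
        return sino
    out = gaussian_filter1d(sino, fwhm_mm / GAUSS_FWHM / geom.radial_spacing, axis=1, mode="constant")
    return gaussian_filter1d(out, fwhm_mm / GAUSS_FWHM / geom.voxel_size, axis=2, mode="constant")


def truth_kernel_size(params: APSFParams, voxel_size: float, cap: int = 151) -> int:
    """Stencil size covering the positron range for the ground-truth blur.

    Unlike the fixed 21/41-voxel correction kernels, the simulation truth
    must reach the full annihilation range (including the stretched range
    in low-density media), otherwise truncation folds distant
    annihilations back toward the source and the simulated data look
    sharper than physics allows.  Capped for memory; the FFT implementation
    makes the cost insensitive to stencil size.
    """
    size = 2 * int(np.ceil(1.5 * params.r0 / voxel_size)) + 1
    return min(size, cap)


def range_blur_for_truth(
    activity: VoxelGrid,
    density: VoxelGrid | None,
    params: APSFParams,
    mode: str,
    kernel_size: int | None = None,
):
    """Blur operator used as simulation ground truth."""
    vs = activity.voxel_size[0]
    if mode == "none":
        return IdentityBlur()
    if kernel_size is None:
        kernel_size = truth_kernel_size(params, vs)
    if mode == "uniform":
        kern = build_uniform_kernel(params, params.rho_ref, kernel_size, vs)
        return ConvolutionBlur(activity.shape, kern)
    if mode == "variant":
        if density is None:
            raise ValueError("variant truth mode requires a density grid")
        # the ground truth weights annihilation by the local density at the
        # annihilation site (positrons barely annihilate in air), unlike the
        # aPSF(r_eq) correction kernels used inside reconstruction
        return VariantSuperpositionBlur(density, params, kernel_size, physical=True)
    raise ValueError(f"unknown truth mode {mode!r}")


def simulate_acquisition(
    activity: VoxelGrid,
    density: VoxelGrid,
    params: APSFParams,
    prc_truth_mode: str,
    geom: ProjectionGeometry,
    total_counts: float,
    seed: int | None,
    detector_fwhm_mm: float = 1.6,
    attenuation: bool = True,
    kernel_size: int | None = None,
    n_subsets: int = 16,
    noiseless: bool = False,
) -> ProjectionData:
    """Simulate a PET acquisition of the given activity distribution.

    The expected sinogram is scaled so its total equals ``total_counts``
    before Poisson sampling; ``noiseless=True`` returns the expectation
    itself (same scaling, no sampling).
    """
    if total_counts <= 0:
        raise ValueError("total_counts must be positive")
    _check_grid(activity, geom)
    blur = range_blur_for_truth(activity, density, params, prc_truth_mode, kernel_size)
    annihilation = activity.like(np.maximum(blur.apply(activity.values), 0.0))
    expected = forward_project(annihilation, geom).values
    if attenuation:
        expected = expected * attenuation_factors(density, geom)
    if detector_fwhm_mm:
        expected = apply_detector_blur(expected, geom, detector_fwhm_mm)
    expected = np.maximum(expected, 0.0)
    total = expected.sum()
    if total <= 0:
        counts = np.zeros_like(expected)
    else:
        expected = expected * (total_counts / total)
        if noiseless:
            counts = expected
        else:
            rng = np.random.default_rng(seed)
            counts = rng.poisson(expected).astype(np.float64)
    subsets = make_subsets(geom.n_angles, n_subsets)
    return ProjectionData(counts, geom, subsets)
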