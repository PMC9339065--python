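"""Digital phantoms: NEMA NU-4 image-quality, two-compartment cardiac, rat thorax.

Each generator returns paired activity/density grids rasterized with the
center-of-voxel membership rule (a voxel belongs to a primitive iff its
center is inside), which makes every phantom deterministic for a given
voxel size.  Activity is in relative concentration units (hot = 1).

Geometry notes
--------------
* The NEMA NU-4 image-quality phantom uses the standard dimensions: 30 mm
  diameter body, 50 mm length, two 8 mm cold chambers (one water, one air)
  and five fillable rods of 1-5 mm diameter on a 7 mm radius.
* The cardiac phantom is a two-compartment chamber (left-ventricle analog
  with a 3 mm wall, right-ventricle analog with a 2 mm wall) inside a
  50 mm diameter cylinder of density 0.4 g/cm^3 emulating lung-like
  surroundings.  Compartment dimensions beyond the wall thicknesses are
  package defaults at rat-heart scale.
* The rat thorax is an ellipsoidal-shell myocardium between lung fields
  (0.3 g/cm^3), a spine insert (1.9) and soft tissue (1.0), with rigid
  axial respiratory translation and an optional anteroapical infarct.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import AIR_DENSITY, VoxelGrid, centered_grid

WATER = 1.0
LUNG = 0.3
BONE = 1.9


# ---------------------------------------------------------------------------
# Geometric primitives
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Cylinder:
    """z-aligned cylinder: center (x, y) mm, radius mm, z extent mm."""

    center: tuple[float, float]
    radius: float
    z_range: tuple[float, float]
    activity: float = 0.0
    density: float = WATER
    name: str = ""

    def contains(self, x, y, z):
        r2 = (x - self.center[0]) ** 2 + (y - self.center[1]) ** 2
        return (r2 <= self.radius**2) & (z >= self.z_range[0]) & (z <= self.z_range[1])


@dataclass(frozen=True)
class Ellipsoid:
    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    activity: float = 0.0
    density: float = WATER
    name: str = ""

    def contains(self, x, y, z):
        return (
            ((x - self.center[0]) / self.semi_axes[0]) ** 2
            + ((y - self.center[1]) / self.semi_axes[1]) ** 2
            + ((z - self.center[2]) / self.semi_axes[2]) ** 2
        ) <= 1.0


@dataclass
class PhantomSpec:
    """Named primitives painted in order onto activity/density grids."""

    primitives: list = field(default_factory=list)

    def paint(self, activity: VoxelGrid, density: VoxelGrid) -> None:
        x, y, z = np.meshgrid(*activity.world_axes(), indexing="ij", sparse=True)
        for prim in self.primitives:
            mask = prim.contains(x, y, z)
            activity.values[mask] = prim.activity
            density.values[mask] = prim.density


def _world_mesh(grid: VoxelGrid):
    return np.meshgrid(*grid.world_axes(), indexing="ij", sparse=True)


# ---------------------------------------------------------------------------
# NEMA NU-4 image-quality phantom
# ---------------------------------------------------------------------------

NEMA_BODY_RADIUS = 15.0
NEMA_LENGTH = 50.0
NEMA_CHAMBER_RADIUS = 4.0
NEMA_CHAMBER_OFFSET = 7.5
NEMA_ROD_DIAMETERS = (1.0, 2.0, 3.0, 4.0, 5.0)
NEMA_ROD_RADIUS_POS = 7.0


@dataclass
class NemaROIs:
    """Analysis regions for the NU-4 metrics."""

    uniform: np.ndarray
    cold_water: np.ndarray
    cold_air: np.ndarray
    rods: dict[int, np.ndarray]
    rod_slices: tuple[int, int]  # z index range of the central rod section
    labels: VoxelGrid | None = None


def gen_nema_nu4(voxel_size: float, shape=None):
    """NEMA NU-4 image-quality phantom.

    Sections along z (50 mm total): 20 mm rod section with five hot rods
    in cold solid, 15 mm uniform hot section, 15 mm section with the two
    cold chambers immersed in hot water.

    Returns ``(activity, density, rois)``.
    """
    if voxel_size > 0.8:
        raise ValueError("voxel_size must be <= 0.8 mm to resolve the 1 mm rod")
    if shape is None:
        nxy = int(np.ceil(2 * (NEMA_BODY_RADIUS + 2.0) / voxel_size))
        nz = int(np.ceil((NEMA_LENGTH + 2.0) / voxel_size))
        shape = (nxy, nxy, nz)
    activity = centered_grid(shape, voxel_size, "activity")
    density = centered_grid(shape, voxel_size, "density")
    density.values[:] = AIR_DENSITY

    z_rod = (-25.0, -5.0)
    z_uniform = (-5.0, 10.0)
    z_cold = (10.0, 25.0)

    spec = PhantomSpec(
        [
            # hot main chamber covering the uniform and cold sections
            Cylinder((0, 0), NEMA_BODY_RADIUS, (z_uniform[0], z_cold[1]), 1.0, WATER, "body"),
            # solid (cold, water-equivalent) rod section
            Cylinder((0, 0), NEMA_BODY_RADIUS, z_rod, 0.0, WATER, "rod-section"),
            Cylinder((NEMA_CHAMBER_OFFSET, 0), NEMA_CHAMBER_RADIUS, z_cold, 0.0, WATER, "cold-water"),
            Cylinder((-NEMA_CHAMBER_OFFSET, 0), NEMA_CHAMBER_RADIUS, z_cold, 0.0, AIR_DENSITY, "cold-air"),
        ]
    )
    rod_centers = {}
    for i, d in enumerate(NEMA_ROD_DIAMETERS):
        ang = 2 * np.pi * i / len(NEMA_ROD_DIAMETERS)
        cx = NEMA_ROD_RADIUS_POS * np.cos(ang)
        cy = NEMA_ROD_RADIUS_POS * np.sin(ang)
        rod_centers[int(d)] = (cx, cy)
        spec.primitives.append(Cylinder((cx, cy), d / 2, z_rod, 1.0, WATER, f"rod-{int(d)}mm"))
    spec.paint(activity, density)

    x, y, z = _world_mesh(activity)
    rois = NemaROIs(
        uniform=np.asarray(
            (x**2 + y**2 <= 11.25**2) & (z >= -2.5) & (z <= 7.5), dtype=bool
        ),
        cold_water=np.asarray(
            ((x - NEMA_CHAMBER_OFFSET) ** 2 + y**2 <= 2.0**2) & (z >= 13.75) & (z <= 21.25),
            dtype=bool,
        ),
        cold_air=np.asarray(
            ((x + NEMA_CHAMBER_OFFSET) ** 2 + y**2 <= 2.0**2) & (z >= 13.75) & (z <= 21.25),
            dtype=bool,
        ),
        rods={},
        rod_slices=(0, 0),
    )
    # central 10 mm of the rod section, per-rod ROI of twice the rod diameter
    zc = (z_rod[0] + z_rod[1]) / 2
    z_axis = activity.world_axes()[2]
    zi = np.where((z_axis >= zc - 5.0) & (z_axis <= zc + 5.0))[0]
    rois.rod_slices = (int(zi[0]), int(zi[-1]) + 1)
    zmask = (z >= zc - 5.0) & (z <= zc + 5.0)
    for d, (cx, cy) in rod_centers.items():
        rois.rods[d] = np.asarray(
            ((x - cx) ** 2 + (y - cy) ** 2 <= d**2) & zmask, dtype=bool
        )
    labels = activity.like(np.zeros(activity.shape, dtype=np.int16), kind="label")
    labels.values[rois.uniform] = 1
    labels.values[rois.cold_water] = 2
    labels.values[rois.cold_air] = 3
    for d, m in rois.rods.items():
        labels.values[m] = 10 + d
    rois.labels = labels
    return activity, density, rois


# ---------------------------------------------------------------------------
# Two-compartment cardiac phantom
# ---------------------------------------------------------------------------

CARDIAC_CYL_RADIUS = 25.0
CARDIAC_CYL_DENSITY = 0.4
#: The chamber is a 3D-printed insert at phantom scale (a large fraction of
#: the 50 mm cylinder), not at literal rat-heart scale: with a lumen small
#: compared to the ~4 mm core of the 82Rb annihilation spread, the
#: uncorrected wall profile has no measurable peak at all.
LV_LUMEN_RADIUS = 8.0
LV_WALL = 3.0
RV_WALL = 2.0
RV_LUMEN_THICKNESS = 3.0
CHAMBER_LENGTH = 15.0
RV_HALF_ANGLE = np.deg2rad(60.0)


def gen_cardiac(voxel_size: float, shape=None):
    """Two-compartment cardiac phantom in a 50 mm lung-density cylinder.

    The left-ventricle analog is an annulus (3 mm lumen radius, 3 mm hot
    wall); the right-ventricle analog is a crescent (3 mm cold lumen,
    2 mm hot wall) wrapped around the +x side.  Returns
    ``(activity, density, landmarks)`` where landmarks are the mm
    endpoints of the two-chamber (LV only) and four-chamber (LV + RV)
    profile lines.
    """
    if voxel_size > 0.5:
        raise ValueError("voxel_size must be <= 0.5 mm to resolve the 2 mm RV wall")
    if shape is None:
        nxy = int(np.ceil(2 * (CARDIAC_CYL_RADIUS + 2.0) / voxel_size))
        nz = int(np.ceil((CHAMBER_LENGTH + 10.0) / voxel_size))
        shape = (nxy, nxy, nz)
    activity = centered_grid(shape, voxel_size, "activity")
    density = centered_grid(shape, voxel_size, "density")
    density.values[:] = AIR_DENSITY

    x, y, z = _world_mesh(activity)
    zmask = (z >= -CHAMBER_LENGTH / 2) & (z <= CHAMBER_LENGTH / 2)
    r = np.sqrt(x**2 + y**2)
    phi = np.abs(np.arctan2(y, x))

    cyl = (r <= CARDIAC_CYL_RADIUS) & (np.abs(z) <= shape[2] * voxel_size)
    density.values[np.broadcast_to(cyl, shape)] = CARDIAC_CYL_DENSITY

    lv_outer = LV_LUMEN_RADIUS + LV_WALL
    rv_lumen_outer = lv_outer + RV_LUMEN_THICKNESS
    rv_outer = rv_lumen_outer + RV_WALL

    lv_wall = (r > LV_LUMEN_RADIUS) & (r <= lv_outer) & zmask
    lv_lumen = (r <= LV_LUMEN_RADIUS) & zmask
    rv_lumen = (r > lv_outer) & (r <= rv_lumen_outer) & (phi <= RV_HALF_ANGLE) & zmask
    rv_wall = (r > rv_lumen_outer) & (r <= rv_outer) & (phi <= RV_HALF_ANGLE) & zmask

    for mask, act, dens in (
        (lv_lumen, 0.0, WATER),
        (lv_wall, 1.0, WATER),
        (rv_lumen, 0.0, WATER),
        (rv_wall, 1.0, WATER),
    ):
        m = np.broadcast_to(mask, shape)
        activity.values[m] = act
        density.values[m] = dens

    extent = min(
        rv_outer + 6.0,
        (shape[0] - 2) / 2 * voxel_size,
        (shape[1] - 2) / 2 * voxel_size,
    )
    landmarks = {
        "two_chamber": ((0.0, -extent, 0.0), (0.0, extent, 0.0)),
        "four_chamber": ((-extent, 0.0, 0.0), (extent, 0.0, 0.0)),
    }
    return activity, density, landmarks


# ---------------------------------------------------------------------------
# Rat thorax with respiratory motion
# ---------------------------------------------------------------------------

THORAX_BODY_SEMI = (16.0, 14.0)
LUNG_SEMI = (6.0, 5.0, 10.0)
LUNG_CENTERS = ((8.5, -2.0, 0.0), (-8.5, -2.0, 0.0))
SPINE_CENTER = (0.0, -11.0)
SPINE_RADIUS = 2.5
HEART_CENTER = (0.0, 3.0, 0.0)
HEART_OUTER_SEMI = (7.0, 7.0, 9.0)
HEART_WALL = 2.5
MOTION_AMPLITUDE_MM = 2.0
INFARCT_HALF_ANGLE = np.deg2rad(45.0)


def gen_rat_thorax(
    voxel_size: float,
    phase: float = 0.0,
    infarct: bool = False,
    shape=None,
    amplitude_mm: float = MOTION_AMPLITUDE_MM,
):
    """Moving rat-thorax phantom: hot myocardial shell between lung fields.

    The whole heart is translated axially by ``amplitude * sin(2 pi phase)``
    emulating the dominant respiratory component.  ``infarct=True`` zeroes
    activity in an anteroapical wedge of the shell (90 degrees of azimuth
    about the anterior direction, apical half), i.e. 1/8 of the shell.
    Returns ``(activity, density)``.
    """
    if not 0.0 <= phase < 1.0:
        raise ValueError("phase must lie in [0, 1)")
    if shape is None:
        n = int(np.ceil(38.0 / voxel_size))
        shape = (n, int(np.ceil(34.0 / voxel_size)), int(np.ceil(40.0 / voxel_size)))
    activity = centered_grid(shape, voxel_size, "activity")
    density = centered_grid(shape, voxel_size, "density")
    density.values[:] = AIR_DENSITY

    x, y, z = _world_mesh(activity)
    body = (x / THORAX_BODY_SEMI[0]) ** 2 + (y / THORAX_BODY_SEMI[1]) ** 2 <= 1.0
    density.values[np.broadcast_to(body, shape)] = WATER

    for cx, cy, cz in LUNG_CENTERS:
        lung = (
            ((x - cx) / LUNG_SEMI[0]) ** 2
            + ((y - cy) / LUNG_SEMI[1]) ** 2
            + ((z - cz) / LUNG_SEMI[2]) ** 2
        ) <= 1.0
        density.values[np.broadcast_to(lung, shape)] = LUNG

    spine = (x - SPINE_CENTER[0]) ** 2 + (y - SPINE_CENTER[1]) ** 2 <= SPINE_RADIUS**2
    density.values[np.broadcast_to(spine, shape)] = BONE

    shift = amplitude_mm * np.sin(2.0 * np.pi * phase)
    hc = (HEART_CENTER[0], HEART_CENTER[1], HEART_CENTER[2] + shift)
    outer = (
        ((x - hc[0]) / HEART_OUTER_SEMI[0]) ** 2
        + ((y - hc[1]) / HEART_OUTER_SEMI[1]) ** 2
        + ((z - hc[2]) / HEART_OUTER_SEMI[2]) ** 2
    ) <= 1.0
    inner_semi = tuple(s - HEART_WALL for s in HEART_OUTER_SEMI)
    inner = (
        ((x - hc[0]) / inner_semi[0]) ** 2
        + ((y - hc[1]) / inner_semi[1]) ** 2
        + ((z - hc[2]) / inner_semi[2]) ** 2
    ) <= 1.0
    shell = outer & ~inner
    density.values[np.broadcast_to(outer, shape)] = WATER
    activity.values[np.broadcast_to(shell, shape)] = 1.0

    if infarct:
        # anterior = +y; wedge of +-45 deg azimuth about anterior, apical half
        phi = np.arctan2(x - hc[0], y - hc[1])  # 0 along +y
        wedge = shell & (np.abs(phi) <= INFARCT_HALF_ANGLE) & (z < hc[2])
        activity.values[np.broadcast_to(wedge, shape)] = 0.0

    return activity, density


__all__ = [
    "PhantomSpec",
    "Cylinder",
    "Ellipsoid",
    "NemaROIs",
    "gen_nema_nu4",
    "gen_cardiac",
    "gen_rat_thorax",
]
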