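"""Voxelized 3D scalar fields (activity, density, labels).

World coordinates follow the voxel-center convention:
``world_mm = origin + index * voxel_size`` with 0-based indices.
Array axes are ordered ``(x, y, z)``; reconstruction treats ``z`` as the
axial (slice) direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Mass density of air at room temperature, g/cm^3.  Used as the fill value
#: for everything outside a phantom and outside the voxel grid.
AIR_DENSITY = 0.0012


@dataclass
class VoxelGrid:
    """A 3D scalar field with voxel size and origin in mm.

    Parameters
    ----------
    values :
        3D array, axis order (x, y, z).
    voxel_size :
        Edge lengths of one voxel in mm, one per axis.
    origin :
        World-mm coordinate of the center of voxel (0, 0, 0).
    kind :
        One of ``"activity"`` (Bq/mL, relative), ``"density"`` (g/cm^3),
        ``"label"`` or ``"value"`` (free-sign scalar field, e.g. a raw
        backprojection).
    """

    values: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    kind: str = "activity"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"VoxelGrid requires a 3D array, got ndim={self.values.ndim}")
        vs = tuple(float(v) for v in np.broadcast_to(self.voxel_size, (3,)))
        if any(v <= 0 for v in vs):
            raise ValueError(f"voxel_size must be positive, got {vs}")
        self.voxel_size = vs
        self.origin = tuple(float(o) for o in np.broadcast_to(self.origin, (3,)))
        if self.kind not in ("activity", "density", "label", "value"):
            raise ValueError(f"unknown grid kind {self.kind!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("VoxelGrid values must be finite")
        if self.kind in ("activity", "density") and np.any(self.values < 0):
            raise ValueError(f"{self.kind} values must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def like(self, values: np.ndarray, kind: str | None = None) -> "VoxelGrid":
        """New grid sharing this grid's geometry."""
        return VoxelGrid(values, self.voxel_size, self.origin, kind or self.kind)

    def world_axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis arrays of voxel-center world coordinates in mm."""
        return tuple(  # type: ignore[return-value]
            self.origin[i] + np.arange(self.shape[i]) * self.voxel_size[i] for i in range(3)
        )

    def world_to_index(self, point_mm) -> np.ndarray:
        """Fractional voxel index of a world-mm point."""
        p = np.asarray(point_mm, dtype=float)
        return (p - np.asarray(self.origin)) / np.asarray(self.voxel_size)

    def same_geometry(self, other: "VoxelGrid", atol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.voxel_size, other.voxel_size, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )


def centered_grid(shape, voxel_size, kind: str = "activity") -> VoxelGrid:
    """Zero-filled grid whose world origin sits at the volume center."""
    shape = tuple(int(s) for s in np.broadcast_to(shape, (3,)))
    vs = np.broadcast_to(voxel_size, (3,)).astype(float)
    origin = tuple(-(s - 1) / 2.0 * v for s, v in zip(shape, vs))
    return VoxelGrid(np.zeros(shape, dtype=np.float64), tuple(vs), origin, kind)


__all__ = ["VoxelGrid", "centered_grid", "AIR_DENSITY", "replace", "field"]
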