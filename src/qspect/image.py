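"""The in-memory 3D image container shared by every pipeline stage.

An :class:`ActivityImage` is a voxel grid with millimetre spacing, a physical
origin (world coordinate of the center of voxel ``(0, 0, 0)``), and a units
tag identifying what the voxels hold: activity concentration (``kBq_per_cm3``),
acquired counts (``counts``), or standardized uptake values (``suv``). Axis
order is (x, y, z) with z along the scanner axis; coordinates follow the
voxel-center convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ArgumentError, DataError

VALID_UNITS = ("kBq_per_cm3", "counts", "suv")


@dataclass
class ActivityImage:
    voxels: np.ndarray
    spacing: tuple[float, float, float]
    units: str
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ArgumentError(f"voxel grid must be 3D, got {self.voxels.ndim}D")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ArgumentError(f"spacing must be three positive values, got {self.spacing}")
        if self.units not in VALID_UNITS:
            raise ArgumentError(f"units must be one of {VALID_UNITS}, got {self.units!r}")
        if self.units == "counts" and np.any(self.voxels < 0):
            raise DataError("count images cannot contain negative voxels")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def voxel_volume_cm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz / 1000.0  # mm3 -> cm3

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates (mm) of voxel centers along one axis."""
        n = self.voxels.shape[axis]
        return self.origin[axis] + self.spacing[axis] * np.arange(n)

    def replace(self, voxels: np.ndarray, units: str | None = None,
                meta: dict | None = None) -> "ActivityImage":
        """New image on the same grid with different voxels/units."""
        return ActivityImage(
            voxels=voxels,
            spacing=self.spacing,
            units=units if units is not None else self.units,
            origin=self.origin,
            meta=dict(self.meta if meta is None else meta),
        )


def centered_grid(extent_mm: tuple[float, float, float],
                  spacing: float) -> tuple[tuple[int, int, int], tuple[float, float, float]]:
    """Shape and origin of a grid of isotropic ``spacing`` covering ``extent_mm``
    and centered on the world origin."""
    if spacing <= 0:
        raise ArgumentError("spacing must be positive")
    shape = tuple(int(np.ceil(e / spacing)) for e in extent_mm)
    origin = tuple(-(n - 1) / 2.0 * spacing for n in shape)
    return shape, origin  # type: ignore[return-value]
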