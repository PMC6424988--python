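"""Voxel grid container shared by every stage of the pipeline.

A :class:`VoxelGrid` is a 3-D scalar field with physical spacing and a value
tag saying what the numbers mean (activity concentration, Hounsfield units,
attenuation coefficients, count density, SUV, ...).  Axes are ``(x, y, z)``
with the last axis being the slice (axial) direction; in-plane spacing is
isotropic.  World coordinates are millimetres at voxel centres with the
origin at the grid centre.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

#: recognised value-semantics tags
KINDS = (
    "activity",       # Bq/mL
    "hu",             # Hounsfield units
    "mu",             # linear attenuation, cm^-1
    "counts",         # counts per voxel
    "count_density",  # counts per cc
    "suv",            # dimensionless
    "label",          # integer class labels
    "mask",           # boolean
)


@dataclass
class VoxelGrid:
    """3-D scalar field with spacing (mm) and a value-semantics tag."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    kind: str = "activity"
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"VoxelGrid needs a 3-D array, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive floats, got {self.spacing}")
        if abs(self.spacing[0] - self.spacing[1]) > 1e-9:
            raise ValueError("in-plane spacing must be isotropic")
        if self.kind not in KINDS:
            raise ValueError(f"unknown grid kind {self.kind!r}; expected one of {KINDS}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_cc(self) -> float:
        """Voxel volume in cm^3 (= mL)."""
        sx, sy, sz = self.spacing
        return sx * sy * sz / 1000.0

    def world_coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis voxel-centre world coordinates in mm (origin at centre)."""
        return tuple(
            (np.arange(n) - (n - 1) / 2.0) * s
            for n, s in zip(self.shape, self.spacing)
        )  # type: ignore[return-value]

    def index_of(self, point_mm: tuple[float, float, float]) -> tuple[int, ...]:
        """Nearest voxel index of a world-mm point (no bounds clipping)."""
        return tuple(
            int(round(p / s + (n - 1) / 2.0))
            for p, s, n in zip(point_mm, self.spacing, self.shape)
        )

    def like(self, data: np.ndarray, kind: str | None = None,
             meta: dict[str, Any] | None = None) -> "VoxelGrid":
        """New grid with the same geometry but different values."""
        return VoxelGrid(data, self.spacing, kind or self.kind,
                         dict(meta if meta is not None else self.meta))


def sphere_mask(grid: VoxelGrid, center_mm: tuple[float, float, float],
                radius_mm: float) -> np.ndarray:
    """Boolean mask of voxels whose centres lie within a world-space sphere."""
    xs, ys, zs = grid.world_coords()
    dx = xs - center_mm[0]
    dy = ys - center_mm[1]
    dz = zs - center_mm[2]
    r2 = (dx[:, None, None] ** 2 + dy[None, :, None] ** 2 + dz[None, None, :] ** 2)
    return r2 <= radius_mm ** 2
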