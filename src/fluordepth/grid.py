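"""Simulation lattice for the SFDI field of view.

Coordinate convention (used everywhere in this package): the tissue surface
is the plane z = 0 and z increases *downward* into the tissue.  A tumor that
"protrudes above the surface" therefore has occupancy at z < 0.  Lateral
coordinates (x, y) are centered on the optical axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GridSpec", "DEFAULT_GRID"]


@dataclass(frozen=True)
class GridSpec:
    """Voxel lattice covering the imaging field of view.

    Defaults give a 101 x 101 lateral grid at 0.5 mm/pixel (50.5 mm field of
    view) and an axial extent of -5 mm (above the surface, to hold protruding
    patient meshes) to +15 mm (deep enough for the 10 mm maximum training
    depth), sampled at 0.5 mm.
    """

    nx: int = 101
    ny: int = 101
    pixel_mm: float = 0.5
    z_min_mm: float = -5.0
    z_max_mm: float = 15.0
    dz_mm: float = 0.5

    def __post_init__(self) -> None:
        if self.nx * self.pixel_mm < 50.0 or self.ny * self.pixel_mm < 50.0:
            raise ValueError("lateral extent must cover the 50 mm field of view")
        if self.dz_mm <= 0:
            raise ValueError("dz_mm must be positive")
        if self.z_max_mm < 10.0:
            raise ValueError("z_max_mm must hold the 10 mm maximum training depth")
        if self.z_min_mm >= 0:
            raise ValueError("z_min_mm must be negative (space above the surface)")

    @property
    def nz(self) -> int:
        return int(round((self.z_max_mm - self.z_min_mm) / self.dz_mm))

    @property
    def x_mm(self) -> np.ndarray:
        """Lateral pixel-center x coordinates (mm), centered on the axis."""
        return (np.arange(self.nx) - (self.nx - 1) / 2.0) * self.pixel_mm

    @property
    def y_mm(self) -> np.ndarray:
        return (np.arange(self.ny) - (self.ny - 1) / 2.0) * self.pixel_mm

    @property
    def z_mm(self) -> np.ndarray:
        """Axial voxel-center coordinates (mm), z > 0 below the surface."""
        return self.z_min_mm + (np.arange(self.nz) + 0.5) * self.dz_mm

    @property
    def voxel_volume_mm3(self) -> float:
        return self.pixel_mm * self.pixel_mm * self.dz_mm

    def to_dict(self) -> dict:
        return {
            "nx": self.nx,
            "ny": self.ny,
            "pixel_mm": self.pixel_mm,
            "z_min_mm": self.z_min_mm,
            "z_max_mm": self.z_max_mm,
            "dz_mm": self.dz_mm,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GridSpec":
        return cls(**d)


DEFAULT_GRID = GridSpec()
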