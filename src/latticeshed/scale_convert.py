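"""Voxel <-> cell <-> physical-size conversions.

The lattice is simulated in 2D with an inflated driver mutation rate ``mu``
(default 1e-3) standing in for the empirical per-division rate ``mu_real``
(default 1e-5).  Each 2D voxel therefore represents ``mu / mu_real`` identical
cells (100 at the defaults), and a simulated cross-section of ``m`` voxels is
mapped to an equivalent 3D spherical tumor whose cross-sectional area matches:

    N = (4/3) * pi * ( sqrt(cells_per_voxel * m / pi) )**3

The linear voxel->cell factor is sqrt(cells_per_voxel) (10 at the defaults),
so a sanctuary radius of R voxels corresponds to R * 10 * cell_diameter in
physical units (0.4 cm at R=20, 1.2 cm at R=60 with 20 um cells).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["ScaleParams", "voxels_to_3d_population", "voxel_radius_to_cm"]


@dataclass(frozen=True)
class ScaleParams:
    """Conversion constants between lattice voxels and physical cells.

    Attributes
    ----------
    mu : float
        Driver mutation rate used in the simulation (per division).
    mu_real : float
        Empirical driver mutation rate (per division).
    cell_diameter_um : float
        Tumor cell diameter in micrometres.
    """

    mu: float = 1e-3
    mu_real: float = 1e-5
    cell_diameter_um: float = 20.0

    def __post_init__(self) -> None:
        if self.mu <= 0 or self.mu_real <= 0 or self.cell_diameter_um <= 0:
            raise ValueError("scale parameters must be positive")

    @property
    def cells_per_voxel(self) -> float:
        """Number of real cells represented by one 2D voxel (area factor)."""
        return self.mu / self.mu_real

    @property
    def linear_cells_per_voxel(self) -> float:
        """Linear voxel->cell factor, sqrt of the area factor."""
        return math.sqrt(self.cells_per_voxel)


def voxels_to_3d_population(m: float, sp: ScaleParams = ScaleParams()) -> float:
    """Equivalent 3D tumor cell count for a 2D cross-section of ``m`` voxels.

    The 2D population is treated as the cross-section of a sphere with equal
    area in cell units: radius r = sqrt(cells_per_voxel * m / pi), and
    N = (4/3) pi r^3.
    """
    if m < 0:
        raise ValueError("voxel count must be non-negative")
    r = math.sqrt(sp.cells_per_voxel * m / math.pi)
    return (4.0 / 3.0) * math.pi * r**3


def voxel_radius_to_cm(r_voxels: float, sp: ScaleParams = ScaleParams()) -> float:
    """Physical radius (cm) of a lattice radius given in voxels."""
    if r_voxels < 0:
        raise ValueError("radius must be non-negative")
    um = r_voxels * sp.linear_cells_per_voxel * sp.cell_diameter_um
    return um * 1e-4  # 1 um = 1e-4 cm
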