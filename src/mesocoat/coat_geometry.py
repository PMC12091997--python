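"""Cell-surface geometry and the molecule census.

Bacterial cells are idealized as spheres (minicells, OMVs) or
spherocylinders (rod-shaped cells: a cylinder capped by two hemispheres).
A protein coat of thickness t occupies the shell between the outer-membrane
surface and the surface offset outward by t.

The census converts a fluorescence-measured coat volume into a molecule
count:

    N = floor( V_measured / c / V_mol )

where c is the fluorescence-enhancement correction (structured-illumination
volumes overestimate true coat volumes; the calibrated default is 3.0) and
V_mol is the per-molecule packing volume from
:func:`mesocoat.structures.molecular_volume`.  Surface densities measured
on minicell segments extrapolate linearly to whole rod-shaped cells.

Conventions: all lengths nm, areas nm², volumes nm³.  A spherocylinder's
`total_length` includes both hemispherical caps, so its surface area is
exactly π·d·L_total.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

# Synthetic stand-in for the per-molecule packing volume of an RFP-tagged
# GBP1 fusion (~93 kDa at ~1.21 Å³/Da), nm³.  Used where no coordinates are
# at hand; pass a measured molecular_volume(...) result for real work.
DEFAULT_RFP_GBP1_VOLUME_NM3 = 113.0

#: default fluorescence-enhancement correction (3D-SIM vs EM volume ratio)
DEFAULT_CORRECTION_FACTOR = 3.0


@dataclass(frozen=True)
class CellGeometry:
    """Sphere or spherocylinder idealization of a bacterial cell, nm."""

    shape: Literal["sphere", "spherocylinder"]
    diameter: float
    total_length: float | None = None  # spherocylinder only, includes caps

    def __post_init__(self) -> None:
        if self.shape not in ("sphere", "spherocylinder"):
            raise ValueError(f"unknown shape {self.shape!r}")
        if self.diameter <= 0:
            raise ValueError("diameter must be positive")
        if self.shape == "spherocylinder":
            if self.total_length is None:
                raise ValueError("spherocylinder requires total_length")
            if self.total_length < self.diameter:
                raise ValueError("total_length must be >= diameter")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0


@dataclass(frozen=True)
class CoatShell:
    """A uniform coat shell of given thickness around a cell."""

    cell: CellGeometry
    thickness: float
    shell_volume: float

    def __post_init__(self) -> None:
        if self.thickness <= 0:
            raise ValueError("thickness must be positive")
        # thin-shell sanity band: V should be close to area × thickness
        approx = surface_area(self.cell) * self.thickness
        if not (0.9 * approx < self.shell_volume < 1.5 * approx):
            raise ValueError(
                f"shell_volume {self.shell_volume:.4g} nm³ outside the thin-shell "
                f"sanity band [{0.9 * approx:.4g}, {1.5 * approx:.4g}]"
            )


@dataclass(frozen=True)
class CensusResult:
    """Molecule count from a measured coat volume."""

    n_molecules: int
    measured_volume: float
    correction_factor: float
    per_molecule_volume: float


@dataclass(frozen=True)
class ExtrapolatedCount:
    """Surface-density extrapolation to a target cell."""

    count: float
    sd: float | None
    density: float
    surface_area: float


def surface_area(cell: CellGeometry) -> float:
    """Surface area in nm²: πd² for a sphere, πd·L_total for a spherocylinder.

    The spherocylinder form is exact because the two hemispherical caps
    together contribute πd² = πd·d and the cylindrical wall πd·(L_total − d).
    """
    if cell.shape == "sphere":
        return math.pi * cell.diameter**2
    return math.pi * cell.diameter * cell.total_length  # type: ignore[operator]


def _solid_volume(cell: CellGeometry) -> float:
    r = cell.radius
    if cell.shape == "sphere":
        return 4.0 / 3.0 * math.pi * r**3
    cyl = cell.total_length - cell.diameter  # type: ignore[operator]
    return math.pi * r**2 * cyl + 4.0 / 3.0 * math.pi * r**3


def shell_volume(cell: CellGeometry, thickness: float) -> float:
    """Volume (nm³) between the cell surface and its outward offset by `thickness`.

    Closed form: the offset of a sphere/spherocylinder is the same solid with
    diameter d+2t (and total_length L+2t), so the shell is a difference of
    two solid volumes.
    """
    if thickness <= 0:
        raise ValueError("thickness must be positive")
    if cell.shape == "sphere":
        inflated = CellGeometry("sphere", cell.diameter + 2 * thickness)
    else:
        inflated = CellGeometry(
            "spherocylinder",
            cell.diameter + 2 * thickness,
            cell.total_length + 2 * thickness,  # type: ignore[operator]
        )
    return _solid_volume(inflated) - _solid_volume(cell)


def make_coat_shell(cell: CellGeometry, thickness: float) -> CoatShell:
    """Build a :class:`CoatShell` with its exact offset-shell volume."""
    return CoatShell(cell, thickness, shell_volume(cell, thickness))


def census_from_volume(
    measured_volume: float,
    per_molecule_volume: float,
    correction_factor: float = DEFAULT_CORRECTION_FACTOR,
) -> CensusResult:
    """Convert a measured coat volume (nm³) into a molecule count.

    The measured volume is first divided by `correction_factor` (the
    fluorescence-enhancement calibration), then by the per-molecule packing
    volume; the count is floor-rounded because molecules are integral.
    """
    if measured_volume <= 0 or per_molecule_volume <= 0 or correction_factor <= 0:
        raise ValueError("all census inputs must be positive")
    n = math.floor(measured_volume / correction_factor / per_molecule_volume)
    return CensusResult(
        n_molecules=n,
        measured_volume=measured_volume,
        correction_factor=correction_factor,
        per_molecule_volume=per_molecule_volume,
    )


def extrapolate_count(
    density: float,
    target: CellGeometry,
    density_sd: float | None = None,
) -> ExtrapolatedCount:
    """Scale a surface density (molecules/nm²) to a whole target cell.

    count = density × surface_area(target); an optional density SD
    propagates linearly.
    """
    if density <= 0:
        raise ValueError("density must be positive")
    if density_sd is not None and density_sd < 0:
        raise ValueError("density_sd must be non-negative")
    area = surface_area(target)
    return ExtrapolatedCount(
        count=density * area,
        sd=None if density_sd is None else density_sd * area,
        density=density,
        surface_area=area,
    )
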