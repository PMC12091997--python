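"""Tomographic conformer metrology: lengths, surface densities, feasibility, FSC.

Conformer length is the shortest Euclidean distance from a GTPase-domain
apex point to the outer-membrane surface — analytic for a spherical
membrane (| ||p − c|| − R |), nearest-neighbor for a segmented point-cloud
membrane.  Densities counted per membrane segment extrapolate to a
whole-cell molecule count; geometric feasibility asks how many folded
("closed") molecules must stack to span a measured coat thickness and
whether an extended ("open") conformer length matches it directly.

Resolution of paired half-volumes is estimated by Fourier shell
correlation: the normalized cross-correlation of Fourier coefficients in
concentric frequency shells, read off at a threshold (default 0.143, the
field standard for independently refined half-maps).

Units: point coordinates and membrane geometry in nm; reported conformer
lengths in Å (1 nm = 10 Å); FSC frequencies in 1/Å and resolutions in Å.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

NM_TO_ANGSTROM = 10.0


# ---------------------------------------------------------------------------
# Membrane representations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SphereSurface:
    """Analytic spherical membrane (center nm, radius nm)."""

    center: np.ndarray
    radius: float

    def __post_init__(self) -> None:
        c = np.asarray(self.center, dtype=float)
        if c.shape != (3,):
            raise ValueError("center must be a 3-vector")
        object.__setattr__(self, "center", c)
        if self.radius <= 0:
            raise ValueError("radius must be positive")

    def distances(self, points: np.ndarray) -> np.ndarray:
        """Shortest distance from each point to the sphere surface (signed → abs)."""
        radial = np.linalg.norm(points - self.center, axis=1)
        return radial - self.radius  # signed; negative = inside

    def area(self) -> float:
        return 4.0 * math.pi * self.radius**2


@dataclass(frozen=True)
class PointCloudSurface:
    """Membrane sampled as a point cloud (n ≥ 100 points, nm)."""

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 100:
            raise ValueError("point-cloud membrane needs >= 100 points of shape (n, 3)")
        object.__setattr__(self, "points", pts)

    def distances(self, points: np.ndarray) -> np.ndarray:
        from scipy.spatial import cKDTree

        d, _ = cKDTree(self.points).query(points)
        return np.asarray(d, dtype=float)


MembraneSurface = SphereSurface | PointCloudSurface


@dataclass
class ConformerField:
    """Apex points (nm) above a membrane surface, optionally segment-labeled."""

    apex_points: np.ndarray
    membrane: MembraneSurface
    segment_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        pts = np.asarray(self.apex_points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] == 0:
            raise ValueError("apex_points must be a non-empty (n, 3) array")
        self.apex_points = pts
        if self.segment_labels is not None:
            labels = np.asarray(self.segment_labels)
            if labels.shape != (pts.shape[0],):
                raise ValueError("segment_labels must have one label per apex point")
            self.segment_labels = labels


@dataclass
class LengthDistribution:
    """Per-conformer lengths (Å) with summary statistics."""

    lengths: np.ndarray
    n: int
    mean: float
    sd: float


@dataclass(frozen=True)
class FeasibilityReport:
    """Closed-stack vs open-conformer account of a measured coat thickness (nm)."""

    measured_thickness: float
    closed_length: float
    open_length: float
    stacked_closed_count: int
    open_consistent: bool


@dataclass
class DensityEnumeration:
    """Whole-cell molecule count from per-segment surface densities."""

    count: float
    sd: float
    mean_density: float
    density_sd: float
    segment_densities: np.ndarray
    total_area: float


@dataclass
class DensityVolumePair:
    """Two equally shaped cubic density grids with a common voxel size (Å)."""

    volume1: np.ndarray
    volume2: np.ndarray
    voxel_size: float

    def __post_init__(self) -> None:
        v1 = np.asarray(self.volume1, dtype=float)
        v2 = np.asarray(self.volume2, dtype=float)
        if v1.shape != v2.shape:
            raise ValueError("the two volumes must have identical shapes")
        if v1.ndim != 3 or len(set(v1.shape)) != 1:
            raise ValueError("volumes must be cubic 3-D grids")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        self.volume1, self.volume2 = v1, v2


@dataclass
class FscResult:
    """FSC curve and the resolution at the requested threshold."""

    frequencies: np.ndarray  # shell centers, 1/Å
    correlations: np.ndarray
    resolution: float  # Å
    threshold: float
    crossed: bool  # False -> curve never fell below threshold (Nyquist-limited)


# ---------------------------------------------------------------------------
# Length metrology
# ---------------------------------------------------------------------------

def measure_lengths(
    field: ConformerField,
    inside_tolerance_nm: float = 1e-6,
) -> LengthDistribution:
    """Shortest apex-to-membrane distances for every conformer, in Å.

    For an analytic sphere the distance is exact; apex points found inside
    the sphere by more than `inside_tolerance_nm` trigger a warning and
    contribute their absolute distance.
    """
    signed = field.membrane.distances(field.apex_points)
    if isinstance(field.membrane, SphereSurface):
        n_inside = int(np.sum(signed < -inside_tolerance_nm))
        if n_inside:
            logger.warning(
                "%d apex point(s) lie inside the membrane sphere; "
                "using absolute distances", n_inside,
            )
    lengths = np.abs(signed) * NM_TO_ANGSTROM
    return LengthDistribution(
        lengths=lengths,
        n=int(lengths.size),
        mean=float(lengths.mean()),
        sd=float(lengths.std(ddof=1)) if lengths.size > 1 else 0.0,
    )


# ---------------------------------------------------------------------------
# Surface-density enumeration
# ---------------------------------------------------------------------------

def enumerate_density(
    field: ConformerField,
    segment_areas: np.ndarray,
    total_area: float | None = None,
) -> DensityEnumeration:
    """Whole-cell molecule count from per-segment densities.

    Each segment contributes density_i = count_i / area_i; the whole-cell
    estimate is mean(density) × total surface area.  The reported count SD
    is the standard error of the mean density scaled by the total area;
    the raw across-segment density SD is also returned.

    `segment_areas[i]` is the area (nm²) of the segment labeled i.  The
    total area defaults to the membrane sphere's area when analytic.
    """
    if field.segment_labels is None:
        raise ValueError("enumerate_density requires segment labels on the field")
    areas = np.asarray(segment_areas, dtype=float)
    if np.any(areas <= 0):
        raise ValueError("every segment area must be positive")
    if total_area is None:
        if isinstance(field.membrane, SphereSurface):
            total_area = field.membrane.area()
        else:
            raise ValueError("total_area is required for a point-cloud membrane")

    n_seg = len(areas)
    counts = np.bincount(field.segment_labels.astype(int), minlength=n_seg)
    if counts.size > n_seg:
        raise ValueError("segment label exceeds the number of provided areas")
    densities = counts[:n_seg] / areas
    mean_d = float(densities.mean())
    sd_d = float(densities.std(ddof=1)) if n_seg > 1 else 0.0
    sem_d = sd_d / math.sqrt(n_seg) if n_seg > 1 else 0.0
    return DensityEnumeration(
        count=mean_d * total_area,
        sd=sem_d * total_area,
        mean_density=mean_d,
        density_sd=sd_d,
        segment_densities=densities,
        total_area=float(total_area),
    )


# ---------------------------------------------------------------------------
# Conformer feasibility
# ---------------------------------------------------------------------------

def feasibility(
    measured_thickness: float,
    closed_length: float,
    open_length: float,
    tolerance: float = 2.0,
) -> FeasibilityReport:
    """Can stacked closed conformers — or one open conformer — span the coat?

    `stacked_closed_count` = ceil(thickness / closed_length): the minimum
    number of folded molecules stacked end-to-end to span the measured
    thickness.  `open_consistent` is true when the extended conformer
    length matches the thickness within `tolerance` (all nm).
    """
    if min(measured_thickness, closed_length, open_length) <= 0:
        raise ValueError("all lengths must be positive")
    if tolerance < 0:
        raise ValueError("tolerance must be non-negative")
    return FeasibilityReport(
        measured_thickness=measured_thickness,
        closed_length=closed_length,
        open_length=open_length,
        stacked_closed_count=math.ceil(measured_thickness / closed_length),
        open_consistent=abs(open_length - measured_thickness) <= tolerance,
    )


# ---------------------------------------------------------------------------
# Fourier shell correlation
# ---------------------------------------------------------------------------

def fsc(pair: DensityVolumePair, threshold: float = 0.143) -> FscResult:
    """Fourier shell correlation of two half-volumes and the threshold resolution.

    Per concentric frequency shell s:

        FSC(s) = Re Σ F1·conj(F2) / sqrt(Σ|F1|² · Σ|F2|²)

    The resolution is 1/frequency at the first downward crossing of
    `threshold`, linearly interpolated between shells.  A curve that never
    crosses reports the Nyquist resolution (2 × voxel) with crossed=False.
    """
    if not (0 < threshold < 1):
        raise ValueError("threshold must lie in (0, 1)")
    v1, v2 = pair.volume1, pair.volume2
    n = v1.shape[0]
    f1 = np.fft.fftn(v1)
    f2 = np.fft.fftn(v2)

    freq = np.fft.fftfreq(n, d=pair.voxel_size)  # 1/Å
    kx, ky, kz = np.meshgrid(freq, freq, freq, indexing="ij")
    kmag = np.sqrt(kx**2 + ky**2 + kz**2)

    df = 1.0 / (n * pair.voxel_size)  # shell width = one frequency step
    shell = np.rint(kmag / df).astype(int)
    n_shells = n // 2 + 1  # up to Nyquist

    flat = shell.ravel()
    cross = np.bincount(flat, weights=(f1 * np.conj(f2)).real.ravel(),
                        minlength=n_shells)[:n_shells]
    p1 = np.bincount(flat, weights=(np.abs(f1) ** 2).ravel(),
                     minlength=n_shells)[:n_shells]
    p2 = np.bincount(flat, weights=(np.abs(f2) ** 2).ravel(),
                     minlength=n_shells)[:n_shells]
    denom = np.sqrt(p1 * p2)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, cross / denom, 0.0)

    freqs = np.arange(n_shells) * df
    nyquist_res = 2.0 * pair.voxel_size

    # first downward crossing of the threshold (skip the DC shell)
    resolution, crossed = nyquist_res, False
    for i in range(1, n_shells):
        if corr[i] < threshold:
            f_lo, f_hi = freqs[i - 1], freqs[i]
            c_lo, c_hi = corr[i - 1], corr[i]
            if c_lo == c_hi:
                f_cross = f_hi
            else:
                f_cross = f_lo + (c_lo - threshold) / (c_lo - c_hi) * (f_hi - f_lo)
            if f_cross > 0:
                resolution, crossed = 1.0 / f_cross, True
            break
    return FscResult(
        frequencies=freqs,
        correlations=corr,
        resolution=float(resolution),
        threshold=threshold,
        crossed=crossed,
    )


# ---------------------------------------------------------------------------
# MRC volume I/O (via gemmi)
# ---------------------------------------------------------------------------

def read_mrc(path: str) -> tuple[np.ndarray, float]:
    """Read an MRC/CCP4 map; returns (grid array, voxel size in Å)."""
    import gemmi

    m = gemmi.read_ccp4_map(str(path))
    grid = np.array(m.grid, copy=True)
    voxel = float(m.grid.spacing[0])
    return grid, voxel


def write_mrc(path: str, volume: np.ndarray, voxel_size: float) -> None:
    """Write a cubic grid as an MRC/CCP4 map with the given voxel size (Å)."""
    import gemmi

    vol = np.ascontiguousarray(np.asarray(volume, dtype=np.float32))
    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(vol)
    n = volume.shape
    m.grid.set_unit_cell(gemmi.UnitCell(
        n[0] * voxel_size, n[1] * voxel_size, n[2] * voxel_size, 90, 90, 90))
    m.update_ccp4_header()
    m.write_ccp4_map(str(path))
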