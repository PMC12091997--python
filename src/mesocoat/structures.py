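"""Atomic structures: PDB parsing, packing volumes, extents, and Cβ-distance screens.

This module supplies the molecular quantities the coat census and the
disulfide-staple design consume:

* :func:`read_pdb` — ATOM/HETATM records into a lightweight :class:`Structure`
  with van der Waals radii attached per element (Bondi table by default).
* :func:`molecular_volume` — volume of the union of vdW spheres on a regular
  grid, optionally inflated by a probe radius.  This is the per-molecule
  volume V_mol that converts a measured coat volume into a molecule count.
* :func:`max_extent` — maximal pairwise atom-center distance, the "length"
  of a conformer as read off a deposited model.
* :func:`cys_pair_screen` — residue pairs whose Cβ atoms fall inside a
  distance window, the standard geometric screen for engineering a
  disulfide staple between two helices.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

# Bondi (1964) van der Waals radii, Å.  Configurable per call; unknown
# elements fall back to DEFAULT_VDW_RADIUS with a logged warning.
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "SE": 1.90,
    "ZN": 1.39,
    "MG": 1.73,
    "NA": 2.27,
    "K": 2.75,
    "CA": 2.31,
    "FE": 2.00,
    "MN": 2.00,
    "CU": 1.40,
    "NI": 1.63,
}
DEFAULT_VDW_RADIUS = 1.70


@dataclass(frozen=True)
class Atom:
    """One atom record; position in Å, vdW radius in Å."""

    serial: int
    name: str
    residue_name: str
    residue_number: int
    chain: str
    position: np.ndarray
    element: str
    vdw_radius: float

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.serial}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)
        if self.vdw_radius <= 0:
            raise ValueError(f"atom {self.serial}: vdw_radius must be positive")


@dataclass
class Structure:
    """An ordered collection of atoms with a free-text identifier."""

    atoms: list[Atom]
    id: str = ""

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("Structure must contain at least one atom")

    def __len__(self) -> int:
        return len(self.atoms)

    def coords(self) -> np.ndarray:
        """(n, 3) array of atom positions in Å."""
        return np.array([a.position for a in self.atoms], dtype=float)

    def radii(self) -> np.ndarray:
        return np.array([a.vdw_radius for a in self.atoms], dtype=float)

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain, None)
        return list(seen)

    def select_chain(self, chain: str) -> "Structure":
        atoms = [a for a in self.atoms if a.chain == chain]
        if not atoms:
            raise KeyError(f"chain {chain!r} not present in structure {self.id!r}")
        return Structure(atoms, id=f"{self.id}:{chain}")

    def residue_atoms(self, chain: str, residue_number: int) -> dict[str, Atom]:
        """Atoms of one residue keyed by atom name."""
        out = {
            a.name: a
            for a in self.atoms
            if a.chain == chain and a.residue_number == residue_number
        }
        if not out:
            raise KeyError(
                f"residue {residue_number} in chain {chain!r} not found "
                f"in structure {self.id!r}"
            )
        return out


@dataclass(frozen=True)
class MolecularVolume:
    """Union-of-spheres volume of a structure, Å³."""

    volume: float
    method: str  # "grid-union" | "monte-carlo"
    grid_spacing_or_samples: float
    probe_radius: float

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise ValueError("volume must be positive")


@dataclass(frozen=True)
class CysPairCandidate:
    """A candidate residue pair for disulfide cross-linking."""

    residue_a: tuple[str, int]
    residue_b: tuple[str, int]
    cb_distance: float

    def __post_init__(self) -> None:
        if self.cb_distance < 0:
            raise ValueError("cb_distance must be non-negative")
        if self.residue_a == self.residue_b:
            raise ValueError("a residue cannot pair with itself")


@dataclass
class CysPairScreen:
    """Result of a Cβ–Cβ window screen.

    candidates: all pairs inside [d_min, d_max], ascending by distance.
    nearest: for every residue in the A list, its single closest partner
    in the B list (regardless of the window).
    """

    candidates: list[CysPairCandidate]
    nearest: dict[tuple[str, int], CysPairCandidate] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# PDB input
# ---------------------------------------------------------------------------

def read_pdb(
    path: str | Path,
    include_hetatm: bool = False,
    radii: Mapping[str, float] | None = None,
    structure_id: str | None = None,
) -> Structure:
    """Read a PDB file into a :class:`Structure`.

    Only the first model is used.  Alternate locations are resolved to the
    highest-occupancy conformer (ties broken by altloc label order).  vdW
    radii are assigned per element from `radii` (default: Bondi table);
    unknown elements get :data:`DEFAULT_VDW_RADIUS` and a logged warning.
    """
    import gemmi

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    table = dict(VDW_RADII if radii is None else radii)

    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"could not parse PDB file {path}: {exc}") from exc

    if len(st) == 0:
        raise ValueError(f"no models in {path}")
    model = st[0]

    atoms: list[Atom] = []
    serial = 0
    for chain in model:
        for residue in chain:
            if residue.het_flag == "H" and not include_hetatm:
                continue
            # altloc policy: group by atom name, keep highest occupancy,
            # ties resolved by file order (gemmi preserves it).
            best: dict[str, gemmi.Atom] = {}
            for at in residue:
                prev = best.get(at.name)
                if prev is None or at.occ > prev.occ:
                    best[at.name] = at
            for at in best.values():
                serial += 1
                elem = at.element.name.upper()
                r = table.get(elem)
                if r is None:
                    logger.warning(
                        "unknown element %r (atom %s/%s %d); using default radius %.2f Å",
                        elem, at.name, residue.name, residue.seqid.num,
                        DEFAULT_VDW_RADIUS,
                    )
                    r = DEFAULT_VDW_RADIUS
                atoms.append(
                    Atom(
                        serial=serial,
                        name=at.name,
                        residue_name=residue.name,
                        residue_number=residue.seqid.num,
                        chain=chain.name,
                        position=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        element=elem,
                        vdw_radius=float(r),
                    )
                )
    if not atoms:
        raise ValueError(f"no ATOM records parsed from {path}")
    return Structure(atoms, id=structure_id or path.stem)


# ---------------------------------------------------------------------------
# Packing volume
# ---------------------------------------------------------------------------

def molecular_volume(
    s: Structure,
    grid_spacing: float = 0.3,
    probe_radius: float = 0.0,
) -> MolecularVolume:
    """Volume of the union of vdW spheres, Å³, on a regular grid.

    Each atom's sphere is inflated by `probe_radius`.  The grid covers the
    bounding box of the structure padded by the largest inflated radius;
    the returned volume is (occupied grid points) × spacing³, which
    converges to the true union volume as the spacing shrinks.
    """
    if grid_spacing <= 0:
        raise ValueError("grid_spacing must be positive")
    if probe_radius < 0:
        raise ValueError("probe_radius must be non-negative")
    coords = s.coords()
    radii = s.radii() + probe_radius
    pad = float(radii.max())
    lo = coords.min(axis=0) - pad
    hi = coords.max(axis=0) + pad

    axes = [np.arange(lo[k], hi[k] + grid_spacing, grid_spacing) for k in range(3)]
    shape = tuple(len(ax) for ax in axes)
    occupied = np.zeros(shape, dtype=bool)

    for center, r in zip(coords, radii):
        # local sub-box around this atom only
        i0 = [np.searchsorted(axes[k], center[k] - r) for k in range(3)]
        i1 = [np.searchsorted(axes[k], center[k] + r, side="right") for k in range(3)]
        sub = [axes[k][i0[k]:i1[k]] for k in range(3)]
        if any(len(ax) == 0 for ax in sub):
            continue
        dx2 = (sub[0] - center[0]) ** 2
        dy2 = (sub[1] - center[1]) ** 2
        dz2 = (sub[2] - center[2]) ** 2
        inside = (
            dx2[:, None, None] + dy2[None, :, None] + dz2[None, None, :]
        ) <= r * r
        occupied[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]] |= inside

    count = int(occupied.sum())
    if count == 0:
        raise ValueError(
            f"grid_spacing {grid_spacing} Å too coarse: no grid point falls "
            "inside any atom sphere"
        )
    return MolecularVolume(
        volume=count * grid_spacing**3,
        method="grid-union",
        grid_spacing_or_samples=grid_spacing,
        probe_radius=probe_radius,
    )


def molecular_volume_mc(
    s: Structure,
    n_samples: int = 1_000_000,
    probe_radius: float = 0.0,
    seed: int = 0,
) -> MolecularVolume:
    """Monte-Carlo rejection estimate of the union-of-spheres volume, Å³.

    Samples uniformly in the padded bounding box and counts hits inside any
    inflated sphere.  Slower-converging than the grid but unbiased; useful
    as an independent cross-check of :func:`molecular_volume`.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    coords = s.coords()
    radii = s.radii() + probe_radius
    pad = float(radii.max())
    lo = coords.min(axis=0) - pad
    hi = coords.max(axis=0) + pad
    box_volume = float(np.prod(hi - lo))

    rng = np.random.default_rng(seed)
    hits = 0
    chunk = 100_000
    r2 = radii**2
    done = 0
    while done < n_samples:
        n = min(chunk, n_samples - done)
        pts = rng.uniform(lo, hi, size=(n, 3))
        d2 = ((pts[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
        hits += int(np.any(d2 <= r2[None, :], axis=1).sum())
        done += n
    volume = box_volume * hits / n_samples
    if volume <= 0:
        raise ValueError("no Monte-Carlo sample fell inside any sphere")
    return MolecularVolume(
        volume=volume,
        method="monte-carlo",
        grid_spacing_or_samples=float(n_samples),
        probe_radius=probe_radius,
    )


# ---------------------------------------------------------------------------
# Extent
# ---------------------------------------------------------------------------

def max_extent(s: Structure, include_radii: bool = False) -> float:
    """Maximal pairwise distance between atom centers, Å.

    With `include_radii` the two endpoint atoms' vdW radii are added,
    giving a surface-to-surface extent.  Exact and order-independent.
    """
    coords = s.coords()
    if len(coords) < 2:
        raise ValueError("max_extent requires at least 2 atoms")

    if include_radii:
        radii = s.radii()
        best = 0.0
        for i in range(len(coords) - 1):
            d = np.linalg.norm(coords[i + 1:] - coords[i], axis=1)
            cand = float(np.max(d + radii[i] + radii[i + 1:]))
            best = max(best, cand)
        return best

    pts = coords
    if len(pts) > 50:
        # the diameter is attained on the convex hull
        try:
            from scipy.spatial import ConvexHull

            pts = coords[ConvexHull(coords).vertices]
        except Exception:  # degenerate (coplanar/collinear) input
            pass
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
    return float(np.sqrt(d2.max()))


# ---------------------------------------------------------------------------
# Cβ screen
# ---------------------------------------------------------------------------

# ideal internal coordinates for a Cβ attached to the backbone
_CB_BOND = 1.521       # CA–CB, Å
_CB_ANGLE = 110.4      # N–CA–CB, degrees
_CB_DIHEDRAL = -122.6  # C–N–CA–CB, degrees


def place_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    bond: float, angle: float, dihedral: float,
) -> np.ndarray:
    """Place atom d given a-b-c so that |c-d| = bond, angle(b,c,d) = angle
    and dihedral(a,b,c,d) = dihedral (degrees).  Standard NeRF construction.
    """
    ang = math.radians(angle)
    dih = math.radians(dihedral)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * math.cos(ang),
            bond * math.sin(ang) * math.cos(dih),
            bond * math.sin(ang) * math.sin(dih),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def virtual_cbeta(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Cβ position built from backbone N/CA/C with ideal tetrahedral geometry.

    Used for glycines, which carry no Cβ but still appear in cross-link
    designs (the substitution to cysteine creates one).
    """
    return place_atom(
        np.asarray(c, float), np.asarray(n, float), np.asarray(ca, float),
        _CB_BOND, _CB_ANGLE, _CB_DIHEDRAL,
    )


def _cbeta_position(s: Structure, chain: str, residue_number: int) -> np.ndarray:
    atoms = s.residue_atoms(chain, residue_number)
    if "CB" in atoms:
        return atoms["CB"].position
    resname = next(iter(atoms.values())).residue_name
    if {"N", "CA", "C"} <= atoms.keys():
        logger.info(
            "residue %s %d (%s) has no CB; using virtual Cβ from backbone",
            chain, residue_number, resname,
        )
        return virtual_cbeta(
            atoms["N"].position, atoms["CA"].position, atoms["C"].position
        )
    raise KeyError(
        f"residue {residue_number} in chain {chain!r} has neither a CB atom "
        "nor a complete N/CA/C backbone to build a virtual one"
    )


def cys_pair_screen(
    s: Structure,
    residues_a: Sequence[int],
    residues_b: Sequence[int],
    d_min: float = 2.0,
    d_max: float = 7.0,
    chain_a: str | None = None,
    chain_b: str | None = None,
) -> CysPairScreen:
    """Screen residue pairs by Cβ–Cβ distance for disulfide-staple design.

    Returns every (a, b) pair with d_min ≤ |Cβ_a − Cβ_b| ≤ d_max sorted by
    ascending distance, plus each A-residue's single nearest B partner.
    Glycines get a virtual Cβ built from their backbone.  Chains default to
    the structure's first chain.
    """
    if not (0 <= d_min < d_max):
        raise ValueError("require 0 <= d_min < d_max")
    default_chain = s.atoms[0].chain
    ca_ = chain_a or default_chain
    cb_ = chain_b or default_chain

    pos_a = {r: _cbeta_position(s, ca_, r) for r in residues_a}
    pos_b = {r: _cbeta_position(s, cb_, r) for r in residues_b}

    candidates: list[CysPairCandidate] = []
    nearest: dict[tuple[str, int], CysPairCandidate] = {}
    for ra, pa in pos_a.items():
        best: CysPairCandidate | None = None
        for rb, pb in pos_b.items():
            if (ca_, ra) == (cb_, rb):
                continue
            d = float(np.linalg.norm(pa - pb))
            pair = CysPairCandidate((ca_, ra), (cb_, rb), d)
            if d_min <= d <= d_max:
                candidates.append(pair)
            if best is None or d < best.cb_distance:
                best = pair
        if best is not None:
            nearest[(ca_, ra)] = best
    candidates.sort(key=lambda p: p.cb_distance)
    return CysPairScreen(candidates=candidates, nearest=nearest)
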