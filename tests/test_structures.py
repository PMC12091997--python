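"""Structures: PDB parsing, packing volume, extent, Cβ screen."""

import math

import numpy as np
import pytest

import mesocoat as mc
from mesocoat.structures import virtual_cbeta

from conftest import random_rotation


def sphere_volume(r: float) -> float:
    return 4.0 / 3.0 * math.pi * r**3


def lens_volume(r: float, d: float) -> float:
    """Overlap volume of two equal spheres of radius r at center distance d."""
    return math.pi * (4 * r + d) * (2 * r - d) ** 2 / 12.0


# ---------------------------------------------------------------------------
# read_pdb
# ---------------------------------------------------------------------------

PDB_TWO_ATOMS = """\
ATOM      1  C   UNK A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  C   UNK A   2       0.000   0.000  10.000  1.00  0.00           C
END
"""

PDB_ALTLOC = """\
ATOM      1  CA AALA A   1       1.000   0.000   0.000  0.60  0.00           C
ATOM      2  CA BALA A   1       2.000   0.000   0.000  0.40  0.00           C
END
"""


def test_read_pdb_minimal_two_atoms(tmp_path):
    p = tmp_path / "two.pdb"
    p.write_text(PDB_TWO_ATOMS)
    s = mc.read_pdb(p)
    assert len(s) == 2
    assert all(a.vdw_radius == mc.VDW_RADII["C"] for a in s.atoms)
    assert np.allclose(s.atoms[1].position, [0, 0, 10])


def test_read_pdb_altloc_keeps_highest_occupancy(tmp_path):
    p = tmp_path / "alt.pdb"
    p.write_text(PDB_ALTLOC)
    s = mc.read_pdb(p)
    assert len(s) == 1
    assert np.allclose(s.atoms[0].position, [1.0, 0.0, 0.0])  # altloc A, occ 0.6


def test_read_pdb_atom_count_matches_independent_parser(tmp_path):
    """Our parser and Biopython agree on the atom count of a synthetic file."""
    from Bio.PDB import PDBParser

    helix = mc.gen_toy_structure("ideal-helix", 15)
    p = tmp_path / "helix.pdb"
    lines = []
    for a in helix.atoms:
        lines.append(
            f"ATOM  {a.serial:5d} {a.name:^4s}{a.residue_name:>4s} {a.chain}"
            f"{a.residue_number:4d}    {a.position[0]:8.3f}{a.position[1]:8.3f}"
            f"{a.position[2]:8.3f}  1.00  0.00          {a.element:>2s}"
        )
    p.write_text("\n".join(lines) + "\nEND\n")

    ours = mc.read_pdb(p)
    theirs = PDBParser(QUIET=True).get_structure("x", str(p))
    n_ref = sum(1 for _ in theirs.get_atoms())
    assert len(ours) == n_ref == len(helix)


def test_read_pdb_errors(tmp_path):
    with pytest.raises(FileNotFoundError):
        mc.read_pdb(tmp_path / "missing.pdb")
    empty = tmp_path / "empty.pdb"
    empty.write_text("REMARK nothing here\nEND\n")
    with pytest.raises(ValueError):
        mc.read_pdb(empty)


# ---------------------------------------------------------------------------
# molecular_volume
# ---------------------------------------------------------------------------

def test_volume_single_sphere_analytic(single_carbon):
    v = mc.molecular_volume(single_carbon, grid_spacing=0.2)
    assert v.volume == pytest.approx(sphere_volume(1.7), rel=0.03)


def test_volume_two_sphere_union_lens_oracle():
    r, d = 1.7, 1.0
    s = mc.Structure(
        [
            mc.Atom(1, "C", "UNK", 1, "A", np.zeros(3), "C", r),
            mc.Atom(2, "C", "UNK", 2, "A", np.array([d, 0, 0]), "C", r),
        ]
    )
    expected = 2 * sphere_volume(r) - lens_volume(r, d)
    v = mc.molecular_volume(s, grid_spacing=0.2)
    assert v.volume == pytest.approx(expected, rel=0.03)


def test_volume_cloud_vs_rejection_sampler():
    """Grid union within 2% of an independent Monte-Carlo rejection estimate."""
    s = mc.gen_toy_structure("sphere-cluster", 50, seed=3)
    coords = s.coords()
    radii = s.radii()
    pad = radii.max()
    lo, hi = coords.min(0) - pad, coords.max(0) + pad
    rng = np.random.default_rng(12345)
    n = 1_000_000
    hits = 0
    for start in range(0, n, 200_000):
        pts = rng.uniform(lo, hi, size=(min(200_000, n - start), 3))
        d2 = ((pts[:, None, :] - coords[None, :, :]) ** 2).sum(2)
        hits += int(np.any(d2 <= radii**2, axis=1).sum())
    oracle = np.prod(hi - lo) * hits / n

    v = mc.molecular_volume(s, grid_spacing=0.3)
    assert v.volume == pytest.approx(oracle, rel=0.02)


def test_volume_monotone_in_probe_and_rigid_invariant(helix20):
    v0 = mc.molecular_volume(helix20, 0.3, probe_radius=0.0).volume
    v1 = mc.molecular_volume(helix20, 0.3, probe_radius=1.4).volume
    assert v1 > v0

    rng = np.random.default_rng(0)
    rot = random_rotation(rng)
    shift = rng.uniform(-20, 20, 3)
    moved = mc.Structure(
        [
            mc.Atom(a.serial, a.name, a.residue_name, a.residue_number, a.chain,
                    rot @ a.position + shift, a.element, a.vdw_radius)
            for a in helix20.atoms
        ]
    )
    vmoved = mc.molecular_volume(moved, 0.3).volume
    assert vmoved == pytest.approx(v0, rel=0.02)


def test_volume_grid_convergence(single_carbon):
    """Halving the spacing changes the estimate by less than 2x the previous change."""
    v1 = mc.molecular_volume(single_carbon, 0.8).volume
    v2 = mc.molecular_volume(single_carbon, 0.4).volume
    v3 = mc.molecular_volume(single_carbon, 0.2).volume
    assert abs(v3 - v2) < 2 * abs(v2 - v1)


def test_volume_degenerate_grid_errors(single_carbon):
    with pytest.raises(ValueError):
        mc.molecular_volume(single_carbon, grid_spacing=50.0)


# ---------------------------------------------------------------------------
# max_extent
# ---------------------------------------------------------------------------

def test_extent_two_atoms(two_carbons_10A):
    assert mc.max_extent(two_carbons_10A) == pytest.approx(10.0)
    assert mc.max_extent(two_carbons_10A, include_radii=True) == pytest.approx(13.4)


def test_extent_matches_brute_force_and_rigid_invariant():
    s = mc.gen_toy_structure("sphere-cluster", 200, seed=1)
    coords = s.coords()
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(2)
    brute = math.sqrt(d2.max())
    assert mc.max_extent(s) == pytest.approx(brute, abs=1e-9)

    rng = np.random.default_rng(4)
    rot = random_rotation(rng)
    moved = mc.Structure(
        [
            mc.Atom(a.serial, a.name, a.residue_name, a.residue_number, a.chain,
                    rot @ a.position + 5.0, a.element, a.vdw_radius)
            for a in s.atoms
        ]
    )
    assert mc.max_extent(moved) == pytest.approx(brute, abs=1e-8)


def test_extent_requires_two_atoms(single_carbon):
    with pytest.raises(ValueError):
        mc.max_extent(single_carbon)


def test_helix_extent_linear_in_residue_count():
    """Ideal helix grows ~1.5-1.6 Å per residue, so extent is linear in n."""
    e20 = mc.max_extent(mc.gen_toy_structure("ideal-helix", 20))
    e40 = mc.max_extent(mc.gen_toy_structure("ideal-helix", 40))
    rise = (e40 - e20) / 20
    assert 1.4 < rise < 1.7


# ---------------------------------------------------------------------------
# cys_pair_screen
# ---------------------------------------------------------------------------

def _toy_cb_structure(positions: dict[int, np.ndarray]) -> mc.Structure:
    atoms = []
    for i, (res, pos) in enumerate(sorted(positions.items()), 1):
        atoms.append(mc.Atom(i, "CB", "ALA", res, "A", pos, "C", 1.7))
    return mc.Structure(atoms)


def test_screen_window_filters_pairs():
    s = _toy_cb_structure({
        1: np.zeros(3),
        10: np.array([3.0, 0, 0]),
        20: np.array([9.0, 0, 0]),
    })
    screen = mc.cys_pair_screen(s, [1], [10, 20], d_min=2, d_max=7)
    assert len(screen.candidates) == 1
    assert screen.candidates[0].residue_b == ("A", 10)
    assert screen.candidates[0].cb_distance == pytest.approx(3.0)
    assert screen.nearest[("A", 1)].residue_b == ("A", 10)


def test_screen_matches_brute_force_on_random_helix_pair():
    rng = np.random.default_rng(8)
    h1 = mc.gen_toy_structure("ideal-helix", 12)
    # second helix: rigid copy shifted sideways, renumbered 101..112
    rot = random_rotation(rng)
    atoms2 = [
        mc.Atom(a.serial + 1000, a.name, a.residue_name, a.residue_number + 100,
                a.chain, rot @ a.position + np.array([6.0, 2.0, 1.0]),
                a.element, a.vdw_radius)
        for a in h1.atoms
    ]
    s = mc.Structure(h1.atoms + atoms2)
    res_a = list(range(1, 13))
    res_b = list(range(101, 113))
    screen = mc.cys_pair_screen(s, res_a, res_b, d_min=2, d_max=7)

    cb = {a.residue_number: a.position for a in s.atoms if a.name == "CB"}
    brute = sorted(
        (np.linalg.norm(cb[i] - cb[j]), i, j)
        for i in res_a for j in res_b
        if 2 <= np.linalg.norm(cb[i] - cb[j]) <= 7
    )
    assert [(p.residue_a[1], p.residue_b[1]) for p in screen.candidates] == [
        (i, j) for _, i, j in brute
    ]
    assert [p.cb_distance for p in screen.candidates] == pytest.approx(
        [d for d, _, _ in brute]
    )


def test_screen_symmetric_under_swap():
    s = _toy_cb_structure({
        1: np.zeros(3),
        2: np.array([4.0, 0, 0]),
        3: np.array([0, 5.0, 0]),
    })
    fwd = mc.cys_pair_screen(s, [1], [2, 3], d_min=2, d_max=7)
    rev = mc.cys_pair_screen(s, [2, 3], [1], d_min=2, d_max=7)
    fwd_pairs = {(p.residue_a[1], p.residue_b[1], round(p.cb_distance, 9))
                 for p in fwd.candidates}
    rev_pairs = {(p.residue_b[1], p.residue_a[1], round(p.cb_distance, 9))
                 for p in rev.candidates}
    assert fwd_pairs == rev_pairs


def test_screen_glycine_uses_virtual_cbeta():
    s = mc.gen_toy_structure("ideal-helix", 12, gly_positions=(5,))
    ref = mc.gen_toy_structure("ideal-helix", 12)
    screen = mc.cys_pair_screen(s, [5], [9], d_min=0, d_max=30)
    ref_screen = mc.cys_pair_screen(ref, [5], [9], d_min=0, d_max=30)
    # virtual Cβ reproduces the built Cβ exactly (same ideal geometry)
    assert screen.candidates[0].cb_distance == pytest.approx(
        ref_screen.candidates[0].cb_distance, abs=1e-9
    )


def test_screen_missing_residue_raises(helix20):
    with pytest.raises(KeyError, match="999"):
        mc.cys_pair_screen(helix20, [999], [5])


def test_virtual_cbeta_geometry():
    """Virtual Cβ sits 1.521 Å from CA at the tetrahedral backbone angle."""
    n = np.array([1.458, 0.0, 0.0])
    ca = np.zeros(3)
    ang = math.radians(111.2)
    c = 1.525 * np.array([math.cos(ang), math.sin(ang), 0.0])
    cb = virtual_cbeta(n, ca, c)
    assert np.linalg.norm(cb - ca) == pytest.approx(1.521, abs=1e-6)
    cos_n = np.dot(n - ca, cb - ca) / (np.linalg.norm(n - ca) * np.linalg.norm(cb - ca))
    assert math.degrees(math.acos(cos_n)) == pytest.approx(110.4, abs=0.01)
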