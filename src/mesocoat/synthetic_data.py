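"""Seeded generators for every input the analysis stages consume.

Each generator is a pure function of its arguments — the same seed gives
byte-identical output — so every fitter in the package can be exercised in
a parameter-recovery loop without microscope, tomograph, or downloads:

* :func:`gen_titration` — Hill-shaped coating curves with Gaussian noise,
  emulating two-fold protein dilution series scored for coating fraction;
* :func:`gen_anisotropy` — single-site binding isotherms with noise;
* :func:`gen_trajectory` — near-linear cumulative assembly counts, with
  optional Poisson counting noise, rising to a plateau;
* :func:`gen_minicell_field` — a spherical minicell decorated with radial
  conformers of fixed true length plus measurement noise, segment-labeled
  by equal-area latitude bands;
* :func:`gen_coat_volume` — the constructive inverse of the molecule
  census (correction × count × per-molecule volume);
* :func:`gen_toy_structure` / :func:`gen_halfmaps` — atomic-structure and
  paired-volume fixtures for the packing-volume, Cβ-screen and FSC stages.
"""

from __future__ import annotations

import math

import numpy as np

from .binding import AnisotropyTitration, isotherm
from .kinetics import AssemblyTrajectory, Titration, hill_curve
from .structures import Atom, Structure, place_atom
from .tomo_measure import ConformerField, DensityVolumePair, SphereSurface


def two_fold_grid(top_nM: float = 2000.0, n_points: int = 8) -> np.ndarray:
    """Two-fold serial dilution grid from `top_nM` downward (nM)."""
    if top_nM <= 0 or n_points < 1:
        raise ValueError("need positive top concentration and n_points >= 1")
    return top_nM / 2.0 ** np.arange(n_points)


def gen_titration(
    km: float,
    hill_slope: float,
    bottom: float,
    top: float,
    conc_grid: np.ndarray | None = None,
    noise_sd: float = 0.03,
    replicates: int = 3,
    seed: int = 0,
) -> Titration:
    """Coating-fraction titration from the Hill model plus Gaussian noise.

    Fractions are clipped to [0, 1] after adding noise (a coating fraction
    cannot leave the unit interval).  Default grid: two-fold dilutions from
    2000 nM, 8 points.
    """
    grid = two_fold_grid() if conc_grid is None else np.asarray(conc_grid, float)
    rng = np.random.default_rng(seed)
    conc = np.repeat(grid, replicates)
    truth = hill_curve(conc, km, hill_slope, bottom, top)
    frac = truth + rng.normal(0.0, noise_sd, size=conc.shape) if noise_sd > 0 else truth
    return Titration(concentrations=conc, fractions=np.clip(frac, 0.0, 1.0))


def gen_anisotropy(
    kd: float,
    r_free: float,
    r_bound: float,
    conc_grid: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
    probe_concentration: float = 250.0,
) -> AnisotropyTitration:
    """Anisotropy titration from the single-site (ligand-excess) isotherm."""
    conc = np.asarray(conc_grid, dtype=float)
    rng = np.random.default_rng(seed)
    sig = np.asarray(isotherm(conc, kd, r_free, r_bound), dtype=float)
    if noise_sd > 0:
        sig = sig + rng.normal(0.0, noise_sd, size=sig.shape)
    return AnisotropyTitration(
        protein_concentrations=conc,
        anisotropy=sig,
        probe_concentration=probe_concentration,
    )


def gen_trajectory(
    rate: float,
    total: float,
    dt: float = 1.0,
    noise_model: str = "none",
    seed: int = 0,
    overrun: float = 1.2,
) -> AssemblyTrajectory:
    """Cumulative molecule counts rising at `rate` (1/s) to a plateau at `total`.

    noise_model "none": exactly linear then flat; "poisson": independent
    Poisson increments of mean rate·dt, cumulative and capped at `total`.
    The series extends `overrun` × the nominal completion time so the
    plateau is visible.
    """
    if rate <= 0 or total <= 0 or dt <= 0:
        raise ValueError("rate, total and dt must be positive")
    t_end = overrun * total / rate
    times = np.arange(0.0, t_end + dt, dt)
    if noise_model == "none":
        counts = np.minimum(rate * times, total)
    elif noise_model == "poisson":
        rng = np.random.default_rng(seed)
        increments = rng.poisson(rate * dt, size=len(times) - 1)
        counts = np.concatenate([[0.0], np.cumsum(increments)])
        counts = np.minimum(counts, total)
    else:
        raise ValueError(f"unknown noise_model {noise_model!r}")
    return AssemblyTrajectory(times=times, counts=counts)


def gen_minicell_field(
    radius_nm: float = 150.0,
    n_conformers: int = 11_760,
    true_length_nm: float = 28.0,
    length_noise_sd_nm: float = 1.5,
    n_segments: int = 20,
    seed: int = 0,
) -> tuple[ConformerField, np.ndarray]:
    """A spherical minicell with radial conformers and equal-area segments.

    Apex points sit at radius + true_length + Gaussian noise along
    area-uniform random directions.  Segments are equal-area latitude bands
    (uniform bands in the direction's z-component), so each has area
    4πR²/n_segments.  Returns (field, segment_areas in nm²).
    """
    if n_conformers <= 0 or n_segments <= 0:
        raise ValueError("n_conformers and n_segments must be positive")
    rng = np.random.default_rng(seed)
    dirs = rng.standard_normal((n_conformers, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    lengths = np.full(n_conformers, float(true_length_nm))
    if length_noise_sd_nm > 0:
        lengths += rng.normal(0.0, length_noise_sd_nm, n_conformers)
    apex = dirs * (radius_nm + lengths)[:, None]
    # z of a uniform direction is uniform on [-1, 1] -> equal-area bands
    band = np.floor((dirs[:, 2] + 1.0) / 2.0 * n_segments).astype(int)
    band = np.clip(band, 0, n_segments - 1)
    membrane = SphereSurface(center=np.zeros(3), radius=radius_nm)
    field = ConformerField(apex_points=apex, membrane=membrane, segment_labels=band)
    areas = np.full(n_segments, membrane.area() / n_segments)
    return field, areas


def gen_coat_volume(
    n_molecules: int,
    per_molecule_volume: float,
    correction_factor: float = 3.0,
) -> float:
    """Constructive inverse of the census: correction × N × V_mol (nm³)."""
    if n_molecules <= 0 or per_molecule_volume <= 0 or correction_factor <= 0:
        raise ValueError("all inputs must be positive")
    return correction_factor * n_molecules * per_molecule_volume


# ---------------------------------------------------------------------------
# Structure fixtures
# ---------------------------------------------------------------------------

# ideal backbone internal coordinates (bond Å / angle deg)
_N_CA, _CA_C, _C_N = 1.458, 1.525, 1.329
_ANG_N_CA_C, _ANG_CA_C_N, _ANG_C_N_CA = 111.2, 116.2, 121.7
_PHI, _PSI, _OMEGA = -57.0, -47.0, 180.0
_CB_BOND, _ANG_N_CA_CB, _DIH_C_N_CA_CB = 1.521, 110.4, -122.6


def gen_toy_structure(
    kind: str = "ideal-helix",
    n: int = 20,
    seed: int = 0,
    gly_positions: tuple[int, ...] = (),
    chain: str = "A",
) -> Structure:
    """Deterministic toy structures for the volumetrics and Cβ-screen stages.

    "sphere-cluster": `n` carbon atoms uniform in a ball whose radius scales
    with n^(1/3).  "ideal-helix": an `n`-residue poly-alanine α-helix built
    from ideal internal coordinates (φ = −57°, ψ = −47°, ~1.5 Å rise per
    residue) with Cβ atoms; residues listed in `gly_positions` (1-based)
    become glycines without a Cβ, exercising the virtual-Cβ fallback.
    """
    if n < 1:
        raise ValueError("n must be positive")
    if kind == "sphere-cluster":
        rng = np.random.default_rng(seed)
        r_ball = 2.0 * n ** (1.0 / 3.0)
        atoms = []
        i = 0
        while len(atoms) < n:
            p = rng.uniform(-r_ball, r_ball, 3)
            if np.linalg.norm(p) <= r_ball:
                i += 1
                atoms.append(Atom(i, "C", "UNK", i, chain, p, "C", 1.70))
        return Structure(atoms, id=f"sphere-cluster-{n}")

    if kind != "ideal-helix":
        raise ValueError(f"unknown toy-structure kind {kind!r}")

    # seed residue 1 by hand, then extend by NeRF
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([_N_CA, 0.0, 0.0])
    ang = math.radians(_ANG_N_CA_C)
    c0 = ca0 + _CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    backbone = [(n0, ca0, c0)]
    for _ in range(1, n):
        n_prev, ca_prev, c_prev = backbone[-1]
        n_i = place_atom(n_prev, ca_prev, c_prev, _C_N, _ANG_CA_C_N, _PSI)
        ca_i = place_atom(ca_prev, c_prev, n_i, _N_CA, _ANG_C_N_CA, _OMEGA)
        c_i = place_atom(c_prev, n_i, ca_i, _CA_C, _ANG_N_CA_C, _PHI)
        backbone.append((n_i, ca_i, c_i))

    atoms = []
    serial = 0
    gly = set(gly_positions)
    for i, (ni, cai, ci) in enumerate(backbone, start=1):
        resname = "GLY" if i in gly else "ALA"
        for name, pos, elem in (("N", ni, "N"), ("CA", cai, "C"), ("C", ci, "C")):
            serial += 1
            r = 1.55 if elem == "N" else 1.70
            atoms.append(Atom(serial, name, resname, i, chain, pos, elem, r))
        if resname != "GLY":
            cb = place_atom(ci, ni, cai, _CB_BOND, _ANG_N_CA_CB, _DIH_C_N_CA_CB)
            serial += 1
            atoms.append(Atom(serial, "CB", resname, i, chain, cb, "C", 1.70))
    return Structure(atoms, id=f"ideal-helix-{n}")


# ---------------------------------------------------------------------------
# Half-map fixtures for FSC
# ---------------------------------------------------------------------------

def gen_halfmaps(
    signal_resolution: float = 20.0,
    noise_sd: float = 0.5,
    shape: int = 64,
    voxel_size: float = 4.0,
    seed: int = 0,
    duplicate_noise: bool = False,
) -> DensityVolumePair:
    """Paired half-volumes: a shared band-limited signal plus per-half noise.

    The signal is white noise low-passed with a cosine rolloff centered on
    1/`signal_resolution`, normalized to unit variance; each half then gets
    independent Gaussian noise of `noise_sd` (or the identical noise when
    `duplicate_noise`, giving an FSC of exactly 1).  With the defaults the
    FSC of the pair crosses 0.143 near `signal_resolution`.
    """
    if signal_resolution <= 2 * voxel_size:
        raise ValueError("signal_resolution must exceed the Nyquist limit (2 × voxel)")
    rng = np.random.default_rng(seed)
    white = rng.standard_normal((shape,) * 3)
    f = np.fft.fftn(white)
    freq = np.fft.fftfreq(shape, d=voxel_size)
    kx, ky, kz = np.meshgrid(freq, freq, freq, indexing="ij")
    kmag = np.sqrt(kx**2 + ky**2 + kz**2)
    kc = 1.0 / signal_resolution
    k0, k1 = 0.9 * kc, 1.1 * kc
    mask = np.clip((k1 - kmag) / (k1 - k0), 0.0, 1.0)
    mask = 0.5 * (1.0 - np.cos(np.pi * mask))  # cosine rolloff, 1 below k0
    signal = np.fft.ifftn(f * mask).real
    signal /= signal.std()

    if noise_sd > 0:
        noise1 = rng.normal(0.0, noise_sd, signal.shape)
        noise2 = noise1 if duplicate_noise else rng.normal(0.0, noise_sd, signal.shape)
    else:
        noise1 = noise2 = np.zeros_like(signal)
    return DensityVolumePair(
        volume1=signal + noise1,
        volume2=signal + noise2,
        voxel_size=voxel_size,
    )
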