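"""Equilibrium LPS binding from fluorescence anisotropy, and the release budget.

A fixed concentration of fluorescent LPS probe is titrated with increasing
protein; the anisotropy signal rises from r_free (probe alone) to r_bound
(saturated).  Under ligand excess (protein ≫ probe) the bound fraction is
the single-site isotherm

    f(c) = c / (Kd + c),     signal(c) = r_free + (r_bound − r_free)·f(c)

and the fit returns (Kd, r_free, r_bound).  When Kd approaches the probe
concentration the ligand-excess approximation over-estimates Kd; the exact
quadratic (probe-depletion) form is available via ``exact_binding=True``.

The budget accounting compares LPS molecules released from the outer
membrane against the total per-cell pool (default 2×10⁶) and, given an
assay volume, against an affinity scale in molar units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

AVOGADRO = 6.02214076e23

#: default total LPS molecules per bacterial cell
DEFAULT_LPS_PER_CELL = 2.0e6


@dataclass
class AnisotropyTitration:
    """Anisotropy signal vs protein concentration (nM) at fixed probe."""

    protein_concentrations: np.ndarray
    anisotropy: np.ndarray
    probe_concentration: float = 250.0  # nM

    def __post_init__(self) -> None:
        self.protein_concentrations = np.asarray(self.protein_concentrations, float)
        self.anisotropy = np.asarray(self.anisotropy, float)
        if self.protein_concentrations.shape != self.anisotropy.shape:
            raise ValueError("concentration and signal arrays must be equal length")
        if np.any(self.protein_concentrations <= 0):
            raise ValueError("protein concentrations must be positive")
        if len(self.protein_concentrations) < 5:
            raise ValueError("need at least 5 titration points")
        if self.probe_concentration <= 0:
            raise ValueError("probe concentration must be positive")


@dataclass
class KdFit:
    """Single-site binding fit: dissociation constant and signal endpoints."""

    kd: float
    r_free: float
    r_bound: float
    rss: float
    converged: bool
    message: str = ""

    def __post_init__(self) -> None:
        if self.converged and self.kd <= 0:
            raise ValueError("kd must be positive")


@dataclass
class LpsBudget:
    """Released LPS against the per-cell pool."""

    total_per_cell: float
    released: float
    released_fraction: float
    sub_percent: bool
    effective_concentration_nM: float | None = None


def _bound_fraction_exact(conc: np.ndarray, kd: float, probe: float) -> np.ndarray:
    """Probe bound fraction from the exact quadratic (no ligand-excess assumption)."""
    s = conc + probe + kd
    return (s - np.sqrt(s**2 - 4.0 * conc * probe)) / (2.0 * probe)


def isotherm(
    conc: float | np.ndarray,
    kd: float,
    r_free: float,
    r_bound: float,
    probe_concentration: float | None = None,
) -> float | np.ndarray:
    """Signal at protein concentration `conc` (nM) for a single-site binder.

    Ligand-excess hyperbola by default; pass `probe_concentration` for the
    exact quadratic form.
    """
    c = np.asarray(conc, dtype=float)
    if probe_concentration is None:
        frac = c / (kd + c)
    else:
        frac = _bound_fraction_exact(c, kd, probe_concentration)
    out = r_free + (r_bound - r_free) * frac
    return float(out) if np.isscalar(conc) else out


def fit_kd(t: AnisotropyTitration, exact_binding: bool = False) -> KdFit:
    """Least-squares (Kd, r_free, r_bound) from an anisotropy titration.

    Unidentifiable data (signal dynamic range below 10% of the maximum
    absolute signal) returns ``converged=False`` rather than raising.
    """
    conc = t.protein_concentrations
    sig = t.anisotropy
    span = float(sig.max() - sig.min())
    scale = float(np.max(np.abs(sig)))
    if scale == 0 or span <= 0.10 * scale:
        return KdFit(kd=np.nan, r_free=np.nan, r_bound=np.nan, rss=np.inf,
                     converged=False, message="signal dynamic range too small")

    probe = t.probe_concentration if exact_binding else None

    def residuals(p: np.ndarray) -> np.ndarray:
        return isotherm(conc, np.exp(p[0]), p[1], p[2], probe) - sig

    # init Kd at the concentration nearest the signal midpoint
    mid = (sig.min() + sig.max()) / 2.0
    kd0 = float(conc[np.argmin(np.abs(sig - mid))])
    p0 = np.array([np.log(kd0), float(sig.min()), float(sig.max())])
    lo = [np.log(1e-6), -np.inf, -np.inf]
    hi = [np.log(1e9), np.inf, np.inf]
    res = optimize.least_squares(residuals, p0, bounds=(lo, hi), method="trf")
    if not res.success:
        return KdFit(kd=np.nan, r_free=np.nan, r_bound=np.nan, rss=np.inf,
                     converged=False, message=res.message)
    rss = float(np.sum(res.fun**2))
    return KdFit(kd=float(np.exp(res.x[0])), r_free=float(res.x[1]),
                 r_bound=float(res.x[2]), rss=rss, converged=True,
                 message=res.message)


def lps_budget(
    released: float,
    total: float = DEFAULT_LPS_PER_CELL,
    assay_volume_L: float | None = None,
) -> LpsBudget:
    """Account released LPS molecules against the per-cell pool.

    Sets ``sub_percent`` when the released fraction is below 1%.  With an
    assay volume (liters) the released amount is also expressed as a molar
    concentration in nM, for comparison against receptor affinities.
    """
    if released < 0 or total <= 0:
        raise ValueError("require released >= 0 and total > 0")
    if released > total:
        raise ValueError("released cannot exceed total")
    fraction = released / total
    conc = None
    if assay_volume_L is not None:
        if assay_volume_L <= 0:
            raise ValueError("assay volume must be positive")
        conc = released / AVOGADRO / assay_volume_L * 1e9  # mol/L -> nM
    return LpsBudget(
        total_per_cell=total,
        released=released,
        released_fraction=fraction,
        sub_percent=fraction < 0.01,
        effective_concentration_nM=conc,
    )
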