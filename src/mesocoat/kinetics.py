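"""Coat assembly kinetics: rates, completion times, and the cooperative coating curve.

Two measurements drive this module:

* time-lapse cumulative molecule counts N(t), from which the assembly rate
  (molecules/s) is the ordinary-least-squares slope over the growth phase
  (by default the points between 10% and 90% of the final count, so the
  lag and the plateau do not bias the slope);
* coating-fraction vs protein-concentration titrations, fitted with the
  four-parameter Hill equation

      f(c) = bottom + (top − bottom) · cʰ / (Kmʰ + cʰ)

  whose half-maximal concentration Km ("coat Km") and slope h quantify the
  sharply cooperative, all-or-none onset of bacterial encapsulation.

The Hill fit is nonlinear least squares with box bounds and a small
fixed-seed multi-start over jittered Km initializations, because steep
slopes (h ≈ 5) leave single-start fits fragile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats


@dataclass
class AssemblyTrajectory:
    """Cumulative molecule counts over time (s)."""

    times: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.counts.shape:
            raise ValueError("times and counts must be 1-D and equal length")
        if len(self.times) < 3:
            raise ValueError("need at least 3 time points")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")


@dataclass
class Titration:
    """Coating fraction vs protein concentration (nM); replicates allowed."""

    concentrations: np.ndarray
    fractions: np.ndarray

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.concentrations.shape != self.fractions.shape:
            raise ValueError("concentrations and fractions must be equal length")
        if np.any(self.concentrations <= 0):
            raise ValueError("concentrations must be positive")
        if np.any((self.fractions < 0) | (self.fractions > 1)):
            raise ValueError("fractions must lie in [0, 1]")
        if len(np.unique(self.concentrations)) < 4:
            raise ValueError("need at least 4 distinct concentrations to fit")


@dataclass
class RateEstimate:
    """OLS growth-phase slope, molecules/s."""

    rate: float
    se: float
    n_points: int


@dataclass
class HillFit:
    """Four-parameter Hill fit of a coating titration."""

    km: float
    hill_slope: float
    bottom: float
    top: float
    rss: float
    converged: bool
    message: str = ""

    def __post_init__(self) -> None:
        if self.converged:
            if self.km <= 0:
                raise ValueError("km must be positive")
            if self.top < self.bottom:
                raise ValueError("top must be >= bottom")
            if not np.isfinite(self.rss):
                raise ValueError("converged fit must have finite rss")


def estimate_rate(
    traj: AssemblyTrajectory,
    growth_lo: float = 0.10,
    growth_hi: float = 0.90,
) -> RateEstimate:
    """Assembly rate as the OLS slope over the growth phase of N(t).

    The growth phase is the set of points whose count lies between
    `growth_lo` and `growth_hi` of the final count (defaults 10%/90%),
    excluding the lag and the plateau.  A flat trajectory has rate 0.
    """
    if not (0 <= growth_lo < growth_hi <= 1):
        raise ValueError("require 0 <= growth_lo < growth_hi <= 1")
    final = float(traj.counts[-1])
    if traj.counts.max() == traj.counts.min():
        return RateEstimate(rate=0.0, se=0.0, n_points=len(traj.times))
    mask = (traj.counts >= growth_lo * final) & (traj.counts <= growth_hi * final)
    if mask.sum() < 3:
        raise ValueError(
            f"only {int(mask.sum())} points in the growth phase "
            f"[{growth_lo:.0%}, {growth_hi:.0%}] of the final count; need >= 3"
        )
    res = stats.linregress(traj.times[mask], traj.counts[mask])
    return RateEstimate(rate=float(res.slope), se=float(res.stderr),
                        n_points=int(mask.sum()))


def completion_time(total_count: float, rate: float) -> float:
    """Minutes to assemble `total_count` molecules at `rate` molecules/s."""
    if total_count <= 0 or rate <= 0:
        raise ValueError("total_count and rate must be positive")
    return total_count / rate / 60.0


def hill_curve(
    conc: float | np.ndarray,
    km: float,
    hill_slope: float,
    bottom: float = 0.0,
    top: float = 1.0,
) -> float | np.ndarray:
    """bottom + (top − bottom)·cʰ/(Kmʰ + cʰ); evaluated in log space for stability."""
    c = np.asarray(conc, dtype=float)
    # cʰ/(Kmʰ+cʰ) = 1/(1 + (Km/c)ʰ) = expit(h·(ln c − ln Km))
    from scipy.special import expit

    frac = expit(hill_slope * (np.log(c) - np.log(km)))
    out = bottom + (top - bottom) * frac
    return float(out) if np.isscalar(conc) else out


def hill_model(conc: float | np.ndarray, fit: HillFit) -> float | np.ndarray:
    """Evaluate a fitted Hill curve at concentration(s) in nM."""
    return hill_curve(conc, fit.km, fit.hill_slope, fit.bottom, fit.top)


def fit_hill(
    t: Titration,
    fix_limits: bool = False,
    n_starts: int = 5,
    seed: int = 0,
) -> HillFit:
    """Nonlinear least-squares Hill fit of a coating titration.

    Fits (Km, h, bottom, top) — or (Km, h) with bottom/top pinned to 0/1
    when `fix_limits` — to all replicate points.  Km is optimized in log
    space with `n_starts` jittered initializations (fixed `seed`), keeping
    the best residual sum of squares.  Never raises on non-convergence;
    inspect `converged`.
    """
    span = float(t.fractions.max() - t.fractions.min())
    if span <= 0.3:
        raise ValueError(
            f"titration dynamic range {span:.3f} too small to constrain a fit (> 0.3 required)"
        )
    conc = t.concentrations
    frac = t.fractions
    km0 = float(np.exp(np.mean(np.log(conc))))  # geometric mean
    b0, t0 = float(frac.min()), float(frac.max())

    if fix_limits:
        def residuals(p: np.ndarray) -> np.ndarray:
            return hill_curve(conc, np.exp(p[0]), p[1], 0.0, 1.0) - frac

        lo = [np.log(1e-9), 1e-6]
        hi = [np.log(1e6), 20.0]
    else:
        def residuals(p: np.ndarray) -> np.ndarray:
            return hill_curve(conc, np.exp(p[0]), p[1], p[2], p[3]) - frac

        lo = [np.log(1e-9), 1e-6, -0.5, -0.5]
        hi = [np.log(1e6), 20.0, 1.5, 1.5]

    rng = np.random.default_rng(seed)
    jitters = np.concatenate([[0.0], rng.uniform(-1.5, 1.5, size=max(0, n_starts - 1))])

    best = None
    for j in jitters:
        p0 = [np.log(km0) + j, 1.0] if fix_limits else [np.log(km0) + j, 1.0, b0, t0]
        p0 = np.clip(p0, lo, hi)
        try:
            res = optimize.least_squares(residuals, p0, bounds=(lo, hi), method="trf")
        except Exception:
            continue
        rss = float(np.sum(res.fun**2))
        if res.success and (best is None or rss < best[0]):
            best = (rss, res)

    if best is None:
        return HillFit(km=np.nan, hill_slope=np.nan, bottom=np.nan, top=np.nan,
                       rss=np.inf, converged=False,
                       message="no multi-start converged")
    rss, res = best
    p = res.x
    if fix_limits:
        km, h, bottom, top = float(np.exp(p[0])), float(p[1]), 0.0, 1.0
    else:
        km, h, bottom, top = float(np.exp(p[0])), float(p[1]), float(p[2]), float(p[3])
        if top < bottom:  # relabel the (rare) inverted solution
            bottom, top = top, bottom
    return HillFit(km=km, hill_slope=h, bottom=bottom, top=top, rss=rss,
                   converged=True, message=res.message)
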