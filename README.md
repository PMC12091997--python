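# mesocoat

Quantitative analysis of mesoscale protein coats on bacterial surfaces.

Interferon-inducible guanylate-binding protein 1 (GBP1) polymerizes into a
shell of roughly ten thousand molecules around cytosol-exposed Gram-negative
bacteria, prying LPS out of the outer membrane and building the platform on
which caspase-4 is recruited. Characterizing that coat quantitatively takes
several unlike measurements — fluorescence volumetrics, time-lapse molecule
counting, equilibrium binding titrations, and cryo-electron tomography —
each with its own estimator. `mesocoat` packages those estimators, plus
seeded synthetic-data generators for every one of them, so each
measurement→estimate loop is reproducible and testable end to end.

## What it computes

* **Molecule census** — a measured coat volume V is converted to a count
  N = ⌊V / c / V_mol⌋, where c is the fluorescence-enhancement correction
  (default 3.0, calibrated against EM) and V_mol is the per-molecule
  packing volume, computed from atomic coordinates as the union of van der
  Waals spheres on a grid (`molecular_volume`).
* **Assembly kinetics** — the assembly rate is the OLS slope of cumulative
  counts over the 10–90% growth phase; the cooperative coating curve is the
  Hill equation f(c) = bottom + (top−bottom)·cʰ/(Kmʰ+cʰ), fitted by bounded
  multi-start nonlinear least squares to give the coat Km and slope h.
* **Equilibrium binding** — anisotropy titrations fitted with the
  single-site isotherm r(c) = r_free + (r_bound−r_free)·c/(Kd+c) (exact
  quadratic probe-depletion form behind a flag), and an LPS release budget
  against the ~2×10⁶-molecule per-cell pool.
* **Conformer metrology** — conformer lengths as shortest apex-to-membrane
  distances; whole-cell counts from per-segment surface densities;
  closed-stack vs open-conformer feasibility (⌈thickness/L_closed⌉ and
  |L_open − thickness| ≤ tol); Fourier shell correlation with resolution at
  the 0.143 threshold.
* **Disulfide design** — Cβ–Cβ distance screening of residue pairs (2–7 Å
  window) with virtual Cβ construction for glycines.

## Worked example

Simulate a coating titration at its reference conditions (truth
Km = 225 nM, h = 5.122, noise sd 0.03, 3 replicates) and refit it:

```bash
$ mesocoat gen titration --seed 42 --out titr.tsv
$ mesocoat hill titr.tsv
{
  "km_nM": 221.61778118503804,
  "hill_slope": 5.078841049278053,
  "bottom": 0.009015062507307794,
  "top": 0.9843479379937258,
  "rss": 0.007841494963556765,
  "converged": true
}
```

The fit recovers the generating Km within 1.5% and the steep slope within
1%: half-maximal coating near 222 nM, with the sharp all-or-none transition
(h ≈ 5) that distinguishes cooperative coat assembly from independent
binding (h = 1).

The census round trip, from the same library in Python:

```python
>>> import mesocoat as mc
>>> v = mc.gen_coat_volume(29_542, 113.0, 3.0)   # nm³, constructive inverse
>>> mc.census_from_volume(v, 113.0, 3.0).n_molecules
29542
>>> mc.completion_time(29_542, 103.0)            # minutes at 103 molecules/s
4.780258899676375
```

A 29,542-molecule coat assembling at 103 molecules/s completes in ≈ 4.8
minutes — inside the 1–6 minute encapsulation window seen in live imaging.

And a synthetic minicell (11,760 conformers of true length 28 nm on a
150-nm-radius membrane, 20 equal-area segments):

```bash
$ mesocoat gen minicell --n 11760 --seed 11 --out mini.tsv
$ mesocoat enumerate mini.tsv --areas mini.tsv.areas.tsv --sphere 0,0,0,150
{
  "count": 11760.0,
  "sd": 94.56827107828946,
  ...
}
$ mesocoat lengths mini.tsv --sphere 0,0,0,150
{
  "n": 11760,
  "mean_A": 279.88235173571337,
  "sd_A": 15.012161614763409
}
```

The density enumeration returns the placed count exactly (equal-area
segments), and the measured length distribution centers on 280 Å — the
extended, membrane-inserted conformer, not the ~129 Å folded one.

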