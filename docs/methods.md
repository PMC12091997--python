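# Methods

`mesocoat` quantifies mesoscale protein coats — shells of ~10⁴ dynamin-family
GTPase molecules (GBP1) that encapsulate cytosol-exposed Gram-negative
bacteria — from four kinds of measurement: fluorescence volumetrics,
time-lapse assembly counts, equilibrium binding titrations, and cryo-ET
point/volume data. This note records the models, the parameters that matter,
the numerical choices, and what the synthetic-data generators do and do not
emulate.

## Molecular volumes and extents

The per-molecule volume V_mol entering the census is the volume of the union
of atomic van der Waals spheres, computed by marking the points of a regular
grid (default spacing 0.3 Å) that fall inside any sphere; each sphere may be
inflated by a probe radius (default 0 Å, i.e. bare vdW union). At 0.3 Å the
grid is within ~3% of analytic sphere and two-sphere-union values and within
2% of a 10⁶-sample Monte-Carlo rejection estimate, which the package also
provides (`molecular_volume_mc`) as an independent estimator. A per-atom
Voronoi partition (which additionally apportions cavity volume) is *not*
implemented: the census needs only one well-defined per-molecule volume, and
the union of spheres is exactly testable against closed forms. Consequently
our V_mol modestly underestimates a Voronoi-style packed volume, which is
immaterial to the round-trip census but should be kept in mind when comparing
absolute volumes across tools.

vdW radii come from the Bondi (1964) element table (`structures.VDW_RADII`),
overridable per call; unknown elements get 1.70 Å with a logged warning.
PDB input is parsed with gemmi; only the first model is read, and alternate
locations resolve to the highest-occupancy conformer (ties by label order).
Residue numbering is taken verbatim from the file.

`max_extent` is the exact maximal pairwise distance between atom centers
(computed on the convex hull for speed, brute force below 50 atoms or when
endpoint radii are requested). It is the operational "length" of a
conformer: ~129 Å for the folded (closed) arrangement of GBP1's C-terminal
helices, ~278 Å for the extended (open) one.

## Disulfide-pair screening

Candidate cysteine staples between two helices are residue pairs whose
Cβ–Cβ distance falls in a window (default 2–7 Å, the range over which an
engineered S–S bond is geometrically plausible). Glycines have no Cβ; a
virtual Cβ is built from the backbone N/CA/C by the standard NeRF
construction with ideal internal coordinates (CA–CB 1.521 Å, N–CA–CB
110.4°, C–N–CA–CB −122.6°). The screen reports Cβ–Cβ distances only; it
does not model the mutated side chains or the S–S bond geometry, so a
"shortest interbond length" quoted for a modeled disulfide is a related but
distinct quantity.

## Cell geometry and the census

Cells are spheres (diameter d) or spherocylinders (diameter d, total length
L *including* both hemispherical caps). With that convention the surface
area has the single closed form A = πd² (sphere) or A = πdL
(spherocylinder), and a coat shell of thickness t is the difference between
the solid inflated by t (d+2t, L+2t) and the original — both verified
against numerical surface-of-revolution and polar-voxel oracles to within
1%.

The census divides a measured coat volume by the fluorescence-enhancement
correction c (default 3.0; calibrated against electron microscopy as a
volume ratio of 3.02, n = 17) and then by V_mol, flooring to an integer.
The inverse operation (`gen_coat_volume`) makes the loop an exact identity,
which is how the procedure is tested. For an RFP-tagged GBP1 fusion the
natural V_mol is the sum of the GBP1 and RFP structure volumes; where no
coordinates are loaded, a synthetic stand-in of 113 nm³ (~93 kDa at
1.21 Å³/Da, a standard protein specific volume) is used — the round trip is
exact for any positive V_mol, so this constant affects no recovered count.

Surface densities measured on minicell segments extrapolate linearly:
count = density × A(target), with any density SD propagated linearly.

## Assembly kinetics

The assembly rate is the ordinary-least-squares slope of cumulative count
vs time restricted to the growth phase — points between 10% and 90% of the
final count (configurable). The windowing removes the lag and plateau,
whose inclusion would bias the slope low; a perfectly flat trajectory is
reported as rate 0. Completion time is count/rate in minutes: at the
measured 103 molecules s⁻¹, a 29,542-molecule coat takes ≈ 4.8 min,
consistent with the observed ~1–6 min encapsulation window.

The coating curve is the four-parameter Hill equation
f(c) = bottom + (top − bottom)·cʰ/(Kmʰ + cʰ), evaluated through a logistic
in log-concentration for numerical stability, and fitted by bounded
nonlinear least squares (scipy TRF) on all replicate points (not means, to
preserve the error structure). Km is optimized in log space; h is bounded
in (0, 20]. Because steep curves leave few points in the transition, the
fit multi-starts from five Km initializations jittered around the geometric
mean of the concentrations (fixed seed), keeping the best residual sum of
squares, and reports `converged=False` instead of raising.

Both free and constrained (bottom = 0, top = 1) variants are provided; the
library default is free. The *recovery protocol* used by the acceptance
script pins the asymptotes: a coating fraction is bounded at 0 and 1 by
construction, and recovery-loop statistics at the default conditions (200
seeds, two-fold grid from 2000 nM, noise sd 0.03, 3 replicates) show the
free fit is biased for steep slopes (mean ĥ 5.95 for truth 5.122) while the
constrained fit is unbiased (mean 5.11, sd 0.54). Even so, the slope's
sampling spread at these conditions is ~10% — single-run estimates of h
carry that uncertainty.

## Equilibrium binding

Anisotropy titrations (fixed fluorescent-LPS probe, protein titrated) are
fitted with the single-site ligand-excess isotherm
r(c) = r_free + (r_bound − r_free)·c/(Kd + c), three free parameters by
bounded least squares with Kd in log space, initialized at the
concentration nearest the signal midpoint. When Kd is comparable to the
probe concentration (e.g. a ~313 nM binder against a 250 nM probe) the
excess approximation overestimates Kd; the exact quadratic
(probe-depletion) form is available via `exact_binding=True`, and a test
demonstrates the difference on quadratic-model data. Signals are
unit-agnostic (mP or % of maximum). Data whose dynamic range is below 10%
of the signal scale are reported unconverged rather than fitted.

The LPS budget is arithmetic made explicit: released/total (default total
2×10⁶ molecules per cell), a flag for the sub-1% regime, and an optional
conversion of the released amount to nM given an assay volume, for
comparison against receptor affinities (caspase-4's Kd scale).

## Conformer metrology

A conformer's length is the shortest Euclidean distance from its
GTPase-domain apex point to the membrane surface — exactly
| ‖p − c‖ − R | for an analytic sphere, nearest-neighbor distance for a
point-cloud membrane (agreeing within twice the cloud's sampling spacing).
Point-to-surface distance, not radial projection, is the definition;
the two coincide on spheres. Apex points found inside the sphere trigger a
warning and contribute their absolute distance. Coordinates are nm at the
boundary; lengths are reported in Å.

Whole-cell enumeration: each labeled segment contributes density =
count/area; the whole-cell count is the mean density × total surface area.
The across-segment density SD is reported raw, and the count SD is the
standard error of the mean density scaled by the total area. For equal-area
segments the estimate reduces to the exact total count, so the synthetic
recovery test is primarily a check of the bookkeeping and of the SD's
coverage. Synthetic segmentations use equal-area latitude bands (uniform in
the direction's z-component).

Geometric feasibility of a measured coat thickness T: the number of folded
conformers of length L_closed that must stack is ceil(T/L_closed), and an
extended conformer of length L_open is consistent when |L_open − T| ≤
tolerance (default 2 nm). For T in the measured 25–27 nm band with
L_closed = 12.89 nm and L_open = 27.8 nm this yields stacks of 2–3 versus a
single open conformer.

## Fourier shell correlation

FSC(s) = Re Σ F₁·F̄₂ / √(Σ|F₁|²·Σ|F₂|²) over concentric Fourier shells one
frequency step wide, up to Nyquist. Resolution is 1/frequency at the first
downward crossing of the threshold (default 0.143, the standard for
independent half-maps), linearly interpolated between shells; a curve that
never crosses reports the Nyquist resolution (2 × voxel) with a flag. No
mask is applied by default. The measure is symmetric in the two volumes and
invariant to positive rescaling of either. MRC/CCP4 volume I/O goes through
gemmi.

## Synthetic data: what it emulates, and what it does not

Every generator is a pure function of an explicit integer seed (byte-
identical reruns; no global RNG state). Defaults are the reference
experimental conditions:
titrations on a two-fold dilution grid from 2000 nM with Gaussian noise sd
0.03 (fraction units) and 3 replicates; anisotropy isotherms with noise at
2% of the dynamic range; trajectories at 103 molecules s⁻¹ to a 29,542
plateau with optional Poisson counting noise; minicells of 150 nm membrane
radius carrying conformers of true length 28 nm with sd 1.5 nm of length
noise, segmented into 20 equal-area bands; half-maps built from a shared
band-limited Gaussian field (cosine rolloff at the target resolution,
default 20 Å) plus independent per-half noise.

The generators reproduce the *statistical structure the estimators assume* —
i.i.d. Gaussian or Poisson noise, uniform placement, radial conformers,
isotropic band-limited signal. They do not emulate image formation
(SIM reconstruction artifacts, tomographic missing wedge, CTF), spatially
correlated segmentation errors, non-uniform coat nucleation, or binding-
signal drift. Passing recovery loops therefore demonstrates that the
estimators are correct and unbiased under their stated assumptions, not
that those assumptions hold for any particular microscope or tomograph.

## Problem sizes and determinism

The shipped tests and the acceptance script run the loops at full
measurement scale — 30,483 length measurements, 11,760 placed conformers, ~350
one-second trajectory steps, 64³ half-maps — which complete in seconds on
one CPU. The acceptance script derives an independent sub-seed per target
from its `--seed` argument, so a single integer reproduces every number it
reports.

## Known limitations

* The union-of-spheres V_mol is not a Voronoi packed volume (no cavity
  apportionment); absolute volumes are tool-dependent.
* The ligand-excess Kd fit is approximate near the probe concentration;
  use `exact_binding=True` there.
* The Hill slope is information-limited on two-fold grids at noise sd 0.03:
  expect ~10% sampling spread in ĥ at those conditions.
* `enumerate_density`'s SD reflects across-segment variation only; it does
  not model segmentation-boundary miscounts.
* Rod-cell extrapolations require the target cell's dimensions, which must
  be supplied by the user; none are bundled.
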