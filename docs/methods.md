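# Methods

`curvsense` reimplements, as a tested pipeline driven by a synthetic data
generator, the analysis used to read membrane-curvature sensing off
coarse-grained simulations of a protein on a wafer-curved bilayer: radially
averaged membrane height profiles with a sigmoid fit and analytic
curvature, area-normalized radial localization statistics for protein
centre-of-mass (CoM) traces, and per-residue protein–lipid contact
profiles.  This note records the models, the parameters that matter, and
the design choices made where the design was genuinely open.

## The membrane model and its curvature

The membrane is radially symmetric about a central pore at
(x_c, y_c) = (16, 20) nm in a 32 × 40 × 33 nm box.  The radially averaged
height of top-leaflet PC headgroups, h(r), is fitted with the generalized
logistic

    h(r) = a + (c − a) / (1 + exp(b (r − x0)))^d

with parameters (a, b, c, d, x0): `c` is the inner (pore-side) plateau,
`a` the outer plateau, `x0` the transition radius, `b` an inverse
transition width, and `d` a shape exponent.  `d = 0` collapses to a flat
membrane; `d = 1` is the symmetric logistic, for which h(x0) is the
plateau midpoint.  The first and second derivatives used downstream are
generated symbolically (sympy) from this expression and lambdified, so the
derivative code cannot drift from the model it differentiates.

Planar curvature and radius of curvature follow from differential
geometry of a graph:

    K(r) = f″(r) / (1 + f′(r)²)^(3/2),      RoC(r) = 1 / |K(r)|.

**Sign convention (used everywhere):** K > 0 where the membrane curves
toward the solvent-exposed side — the band that looks *concave* to a
protein above the membrane; K < 0 is convex.  Points with |K| below
`flat_threshold` (default 0.01 nm⁻¹, i.e. RoC > 100 nm) are labelled flat;
the threshold is exposed because no principled universal value exists.

Default geometry: a = 15 nm, c = 11 nm (pore depth 4 nm), x0 = 8.5 nm,
b = 0.527 nm⁻¹, chosen so the curvature extrema — the concave and convex
bands — sit near r ≈ 6 nm and r ≈ 11 nm, matching the taper radii
(6 and 11 nm) of the wafer the geometry emulates.  All are config-exposed.

### Fitting

`fit_sigmoid` is a bounded nonlinear least-squares fit
(`scipy.optimize.curve_fit`).  The deterministic initial guess takes a and
c from the outer/inner plateau means of a lightly smoothed profile, x0
from the mid-gap crossing, b from the 25–75% transition width
(= 2 ln 3 / b for the symmetric logistic), and d = 1; a second generic
start protects against bad basins, and the returned fit never has a larger
residual sum of squares than the initial guess.  The model is
over-parametrized in its flat limits, so the contract is on fitted *curve
values*, never on parameter uniqueness; an exactly constant profile
short-circuits to the flat limit rather than exercising a singular
Jacobian.  Profiles are pooled over frames before fitting (a per-replica
mode is available by fitting per-replica frame lists).

## Localization statistics

Protein CoM positions are reduced to the radial distance
r = √((x − x_c)² + (y − y_c)²) with no periodic wrapping — the pore is
centred and the analysis range stays inside the box; this is a documented
limitation, not an approximation error, for centred-pore geometries.

* **Histograms:** 100 equal bins over [0, 25] nm, normalized so the bin
  sum is exactly 1.  **Heatmaps:** absolute distances |x − x_c|, |y − y_c|
  on a 50 × 50 grid over [0, 16] × [0, 20] nm, also sum-1; out-of-range
  points are counted and reported, never silently dropped.
* **RDF normalization:** each bin's count is divided by its annulus area
  *clipped to the box* and by the species' global area density, so a
  uniformly distributed species reads RDF = 1 ("bulk") in every bin.
  Clipping uses the exact closed-form circle–rectangle intersection area
  (piecewise analytic integration), not sampling: without exact clipping
  the uniform ⇒ 1 property fails near and beyond the box half-widths.
* **Display truncation:** distributions are displayed up to half the
  shortest in-plane box vector (16 nm); values beyond are computed and
  flagged, not discarded.
* **KDE:** `scipy.stats.gaussian_kde` with Scott's-rule bandwidth
  (overridable), the conventional default of that routine.
* **Peaks:** argmax bin centre with ties broken toward smaller r and
  reported; a flat distribution returns a no-peak flag.  For *verdicts*
  (below) a peak must additionally reach 2× bulk enrichment in a bin with
  ≥ 100 raw counts: annuli near r = 0 have near-zero area, so a handful of
  stray counts there would otherwise produce arbitrarily large spurious
  RDF values.  The thresholds come from the a-priori counting statistics
  of the default trace lengths, not from any particular run.  Lipid RDFs
  pool far fewer samples (hundreds of PIP2 headgroups), so their peak
  searches use a count floor scaled to the pooled count (~1%, at least 2)
  with the same purpose.

## The synthetic generator

The generator defines the study conditions; every downstream stage is
tested against it.  It emulates three features of the reference system and
deliberately nothing else:

1. **Geometry:** lipid sites uniform in the box plane, headgroups at
   h(r) + N(0, σ) with σ = 0.3 nm (typical coarse-grained headgroup
   roughness), glycerol and two tail beads offset toward the bilayer
   midplane, a mirrored bottom leaflet, four beads per lipid.  Default
   3900 PC lipids over both leaflets (≈ 0.65 nm² per lipid).
2. **Curvature-sorted PIP2** (2.5% of lipid sites, top leaflet only):
   PIP2 identity is assigned with probability ∝ exp(w·K(r)), rescaled so
   the marginal PIP2 fraction stays nominal.  Positive w enriches PIP2 at
   concave and depletes it at convex curvature; the default w = 12 nm
   gives ≈ 3× enrichment at the concave band and ≈ 3× depletion at the
   convex band.  Sorting is treated as substrate-geometry-driven and
   protein-independent.
3. **Protein localization:** a Metropolis random walk of the CoM in the
   membrane plane (Gaussian proposals, σ = 1 nm; moves outside the box
   rejected; z rides 0.5 nm above the local surface) under

       U(r) = − w_hydro · A_convex(r) − w_pip2 · A_PIP2(r)   [kT],

   where A_convex is the normalized convexity score (clipped −K, max 1)
   and A_PIP2 the normalized local PIP2 area density measured from the
   generated frames (1-nm counting annuli, exact clipped areas, light
   3-point smoothing so shot noise cannot define the energy minimum).
   The stationary radial occupancy is p(bin) ∝ area(bin)·exp(−U), which
   `boltzmann_radial_occupancy` evaluates by direct summation — the
   independent oracle the Metropolis sampler is tested against
   (total-variation distance ≈ 0.01–0.02 at 10⁵ steps).

The qualitative free-energy picture of competing hydrophobic and
electrostatic attractions is made concrete as this two-term linear energy —
a minimal parametrization able to reproduce all three localization
phenotypes.  The three terminal-helix analogues scale w_hydro with their
embedded hydrophobic residue counts (full : split : short = 5 : 2 : 2,
residues {6, 10, 17, 44, 52} / {6, 10} / {44, 52}), at 1.2 kT per embedded
residue — a plausible per-residue insertion free energy for a
coarse-grained amphipathic anchor.  w_pip2 = 4 kT is identical for all
three, since PIP2 binding is unaffected by the terminal helix.  With these
defaults the convex minimum (−6 kT) beats the PIP2 minimum (−4 kT) only
for the full analogue, reproducing the intended matrix: all variants peak
in the convex band on PC-only membranes; with PIP2 the full analogue keeps
its convex peak while split/short move to the concave band.

Seeding: one master seed; per-frame and per-replica streams are derived
through fixed `SeedSequence` offsets, so identical configurations are
bit-identical, including all written artifacts (the run manifest hashes
the scientific config and excludes the output path).

**What the generator does not emulate** — and hence what passing tests do
not show about real trajectories: no bead-level dynamics or forces, no
membrane undulations beyond white headgroup noise, no protein footprint or
orientation coupling (the protein is a point CoM for localization and a
planted bead chain for contacts), no lipid diffusion or inter-frame
correlation (frames are independent snapshots), and no wafer beads.
Contact profiles are *planted* constructions: residues listed as embedded
are placed at tail depth, PIP2-binding basic residues at headgroup level,
everything else above the membrane, so contact recovery tests the counting
machinery, not binding physics.  The 55-residue sequence is a synthetic
analogue with the key hydrophobic (L6, I10, V17, Y44, M52) and basic (K24,
K28, K38–K40) residues at their literature positions and no other
hydrophobic-class or basic-class letters elsewhere.

## Contacts and tilt

A contact is a (protein bead, target bead) pair within a cutoff under the
3-D minimum-image convention, counted with a periodic cKD-tree and tested
for exact equality against the quadratic enumeration.  Target groups:
hydrophobic tails = tail beads, PIP2 headgroups = PIP2 head beads;
glycerol belongs to neither.  The cutoff defaults to 0.6 nm (the
conventional default of the standard contact tool) and conclusions on
synthetic data are checked to be stable over 0.5–0.7 nm.  Pair counts are
the default; per-residue means are averaged over all frames of all
replicas with per-replica means retained for dispersion.

The tilt angle is a declared stand-in for a rotation-matrix orientation
analysis: the angle between the largest-variance principal axis of the
protein beads (orientation fixed by a reference residue pair, default
first→last) and the membrane normal, in [0°, 180°].  A perfectly straight
bead rod is fine (its principal axis is unique); geometry without a unique
largest-variance axis raises a degenerate-geometry error.

## Numerical choices and problem sizes

* Radial height profile: 0.5 nm annuli, empty annuli flagged (NaN), never
  interpolated.
* Curvature evaluated on 512-point grids; RoC reported as ∞ where K = 0.
* Default analysis sizes: 8 replicas × 10⁴ Metropolis steps per condition,
  5–10 membrane frames per condition; the occupancy-equivalence check uses
  a single 10⁵-step chain.  These sizes put every Monte-Carlo assertion
  comfortably inside its a-priori sampling tolerance while keeping the
  full suite around a minute.
* Uniform-species RDF checks assert the ±0.1 bulk band only on bins whose
  expected count makes that a ≥ 4.4σ statement (≥ ~1900 counts at n = 10⁵),
  and a 5σ per-bin band everywhere displayed: the innermost 0.25 nm annuli
  hold ~15 expected counts at n = 10⁵, so a fixed ±0.1 assertion there
  would test shot noise, not the normalization.

## Known limitations

* Radial symmetry is assumed throughout even though the box is
  rectangular; all statistics in the analysis are radial, and the RDF
  area-clipping handles the box edges exactly.
* Eq.-1 distances are not minimum-image; traces that wander more than half
  a box length from the pore would need unwrapped coordinates.
* The sigmoid family cannot represent arbitrary profiles (e.g. a full
  circular cap); local fits over monotone windows recover local curvature
  to a few percent, which is the intended use.
* The verdict is a peak-region readout, not a free-energy estimate; no
  umbrella sampling or binding thermodynamics is implied.
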