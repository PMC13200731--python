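# Methods

This note documents the models, conventions and numerical choices behind
each analysis stage, what the synthetic-data generators do and do not
emulate, and the known limitations.

## Coordinate and data conventions

All coordinates are micrometres in a continuous frame; nothing carries
pixel or voxel semantics. Reconstructions follow SWC conventions with a
single soma root node; SACs are axonless, so every non-soma SWC type code
is treated as dendrite (unknown codes are accepted with a warning). The
soma is one node whose radius encodes an equivalent-circle radius when
soma area comes from ROI measurements. Stimulus directions are motion
directions in degrees, counter-clockwise with 0° = +x, restricted to the
12 × 30° grid of the grating protocol (3 s per direction per epoch).

## Single-cell morphometry

Measurements are made in the en-face (xy) projection, matching flat-mount
imaging of planar SAC arbors.

* **Sholl analysis** uses circles in the xy projection, not 3D spheres.
  An edge contributes one intersection per sign change of its radial
  distance from the soma; a re-entrant edge therefore counts twice, and a
  tangency counts zero. The circle itself is assigned to the *inside*, so
  a node lying exactly on a circle yields exactly one crossing for its
  in/out edge pair — this keeps every morphometric invariant under
  insertion of pass-through nodes. The normalized profile divides the
  radial distance R (maximum node distance from the soma) into ten
  half-open bands ((k−1)R/10, kR/10] and averages the 1 µm-step counts in
  each; empty bands contribute 0. R is the maximum *node* distance rather
  than the hull radius; the two differ negligibly for radial arbors.
* **Branch decomposition**: a branch is a maximal unbranched path between
  soma, branch point, or tip. Its level is 1 + the number of branch points
  strictly between it and the soma (primary dendrites are level 1); the
  soma never counts as a branch point regardless of trunk count.
* **Caliber** of a branch is the *median* node diameter along it, robust
  to tapering tips and analogous to measuring one perpendicular line per
  dendrite. A cell is hypertrophic iff some branch caliber strictly
  exceeds 1 µm (a caliber of exactly 1 µm is not hypertrophic).
* **Self-crossings** replace discrete single-z-plane counting with a
  continuous z-slab: an unordered edge pair counts iff the two edges share
  no node, their xy projections properly cross (interior intersection),
  and their interpolated z values at the crossing differ by ≤ 1 µm
  (flag-exposed). Pairs sharing a node — parent/child or siblings at a
  branch point — are excluded.
* **Field area** is the 2D convex hull of all node positions
  (scipy Qhull); collinear degenerate inputs raise rather than return 0.
* **Soma area** is the absolute shoelace area of the traced polygon;
  self-intersecting polygons are rejected (shapely validity test).

## Mosaic spacing

Two measures are computed, because published mosaic analyses report a
"regularity index ratio against a random distribution" without a formula:

* **Density recovery profile**: neighbour counts in 5 µm annuli out to
  100 µm around each reference cell, converted to cells/mm² by the exact
  annulus area. References are restricted to a guard zone at least
  `max_radius` from every window edge, so no annulus is censored; border
  correction by guard zone (not toroidal wrapping) because retinal fields
  are not periodic. The effective radius converts the near-cell density
  deficit into the radius of an equivalent hard disc:
  r_eff = √( Σ_b max(0, D̄ − D_b)·A_b / (π·D̄) ), summed over annuli below
  the first annulus whose density reaches the overall mean density D̄.
  The max(0,·) makes r_eff a slightly positively biased estimator on pure
  noise (≈1–3 µm for Poisson patterns at the default settings), which is
  negligible against real exclusion radii of 20–30 µm.
* **Nearest-neighbour regularity index** RI = mean/SD of NN distances.
  Neighbours are searched over all points; references are restricted to
  points farther than the maximum observed NN distance from every edge,
  so each reference's true nearest neighbour is observed. For a 2D
  Poisson process RI → (1/2)√(4π/(4−π)) ≈ 1.913. The headline
  **regularity index ratio** divides the observed RI by the mean RI of
  `n_sim = 99` binomial (fixed-count uniform) patterns in the same
  window, seeded for reproducibility. Zero NN spread (a perfect lattice)
  reports an infinite RI with a warning rather than an error.

## Lamination

Intensity samples are mapped affinely from the (inner, outer) IPL
boundary positions onto depth [0, 1] (depth 0 adjacent to the GCL; an
`invert` flag handles the opposite section orientation), averaged in 20
equal bins and normalized to sum 1 — making profiles comparable across
sections with different IPL thicknesses and staining strengths. The
scalar fed to group statistics is **band compactness**: the fraction of
profile mass within ±1 bin of the two highest strict local maxima
(union, so overlapping windows are not double-counted). This is an
explicit, testable stand-in for proprietary stratification scores; it is
documented as an interpretation, not a claim of equivalence to any
particular plugin's internal statistic. Profiles without two local maxima
(e.g. uniform) raise rather than returning a misleading score.

## Synaptic puncta

Puncta are filtered by membrane-GFP mask membership and size ≥ 0.5 µm.
Distance from the soma is 3D Euclidean by default — the convention of
surface-object statistics in commercial reconstruction software — with
geodesic (along-arbor, via the nearest tree node) as an option because
either reading of "distance from the soma" is defensible. Normalized
radius divides by the arbor radius (maximum node distance); the
distribution uses ten equal bins, and the headline scalar is the fraction
beyond 2/3 — the outer third, where SAC synaptic outputs reside. A
punctum farther than 1.1× the arbor radius triggers a warning and is
clipped into the outermost bin. Puncta sizes are diameters; a
sphere-equivalent volume (π/6)·d³ is reported alongside for comparability
with volume-based measurements.

## Direction selectivity

* **DSI** is the vector-sum index on the 12 mean responses,
  |Σ R_j e^{iθ_j}| / Σ R_j. Means over epochs are taken first (the
  alternative, averaging per-epoch vector norms, is biased upward by
  noise).
* **Von Mises fit**: R(θ) = b + a·exp(κ(cos(θ−μ)−1)) by bounded
  least squares (a, b ≥ 0, 0 ≤ κ ≤ 100), initialised at the
  resultant-vector angle with b = min, a = max−min, and κ restarts at
  {2, 0.5, 8}; the best of the restarts is kept. Goodness is the
  coefficient of determination R² on the 12 means; flat tuning
  (zero variance) has undefined R² and reports −inf with a warning.
* **Tuning width** is computed analytically from the fitted κ:
  FWHM = 2·arccos(1 − ln2/κ), valid for κ ≥ ln2/2; flatter tuning never
  falls to half maximum and returns a 360° sentinel. The analytic route
  is used because a 30°-sampled raw curve is far too coarse for a direct
  half-maximum reading.
* **DSGC classification** applies, in order: total spikes ≥ 400;
  DSI > 0.37; fit R² > 0.5; and mean spikes ≥ 10 in the preferred
  direction, taken as the sampled grid direction nearest the fitted μ
  (spikes exist only at sampled directions). All intermediate metrics are
  reported whether or not a unit passes.

## Statistics

Student's pooled-variance t-test is the two-group default (Welch behind a
flag); degenerate zero-variance input resolves to p = 1 (equal means) or
p = 0 with a warning (unequal). ANOVA uses scipy's F-test with Tukey HSD
adjusted pairwise p-values; Kruskal–Wallis uses tie-corrected ranks with
Dunn's z-tests and Bonferroni adjustment (implemented in-package). The
two-sided Fisher exact test uses hypergeometric probability ordering —
the convention under which 13/16 vs 1/12 hypertrophic cells gives
p = 0.0003. Curve families (Sholl, branch level, puncta distributions)
are reduced per cell to trapezoid AUCs on a shared x-grid and compared by
t-test on the AUC samples. ROI fluorescence normalization supports ratio
(no-enrichment baseline 1) and subtraction (may be negative, reported
as-is).

## Synthetic-data generators

Every generator is a pure function of its parameter set, seed included:
identical inputs give bitwise-identical outputs.

**Arbors** grow from `n_primary` (default 4) trunks at evenly spaced
angles with jitter; 16 µm (±15 %) segments extend outward with angular
noise and a mild radial bias, and stop past a 120 µm field radius. Two
mechanisms interact:

* *Stochastic bifurcation*: each surviving segment branches with
  probability 0.77 (control), at a mean half-angle of 0.55 rad.
* *Space competition*: a tip extending into territory already occupied by
  foreign dendrite (nodes within 8.75 µm, excluding its own recent path)
  terminates with probability 1 − 0.4^k for k nearby nodes, and its
  branching is suppressed by a factor 0.2^k. This saturates total cable
  near the arbor's tiling density, so branch-point count scales roughly
  linearly with branch probability while total length moves weakly —
  the dissociation seen in *Pten*-deficient SACs, where branching nearly
  doubles at near-normal cable length and unchanged field size. Pure
  compounding growth cannot reproduce this (branching ratios explode),
  which is why space competition is part of the model rather than an
  ornament.

The knockout phenotype multiplies the bifurcation probability by 1.7 —
which saturates the per-segment probability at 1, i.e. knockout tips
attempt a branch at every internode — and renders one primary trunk
hypertrophic (1.4 µm caliber vs the 0.6 µm control caliber, which tapers
distally). Field radius is untouched. With these defaults, 50-seed batches
give control means of ~111 branch points and ~4.4 mm cable, and a
KO/control branch-point ratio of ~1.62 (batch SD ≈ 0.04); the segment
length default of 16 µm was chosen because shorter internodes cannot
reach the observed control cable length and branch count simultaneously
under space competition. Arbors are planar to within ±1 µm of z jitter,
which exercises the self-crossing z-slab logic.

**Mosaics** are homogeneous Poisson (random) or simple sequential
inhibition (hard-core exclusion; candidates within the exclusion radius
of accepted points are rejected, with a bounded attempt budget that
raises on infeasible packing). Sequential inhibition is sufficient to
separate regular from random baselines; it is not a model of the
developmental process that produces real mosaics.

**Depth profiles** are two Gaussian bands (defaults centred at normalized
depths 0.27 and 0.62, σ = 0.05) plus non-negative Gaussian noise, sampled
densely across a configurable source-coordinate span.

**MEA units** are Poisson spikers: direction-selective units follow the
von Mises rate law (defaults κ = 2, 20 spikes/epoch at preferred, 2 at
baseline, 30 epochs); untuned units fire direction-independently
(5 spikes/epoch). Poisson noise is an assumption — recorded spike counts
are often overdispersed, so real false-positive rates may differ from the
simulated <5 %.

**Puncta** are placed uniformly along arbor cable beyond a normalized
radius of 2/3, with truncated-normal sizes; an optional decoy fraction
adds off-mask or undersized records that the filtering stage must remove.

What passing tests on these generators shows: the *analysis* code is
correct on data with the assumed statistical structure. What it does not
show: robustness to reconstruction errors, soma mis-assignment,
non-planar arbors, segmentation artefacts in puncta, overdispersed or
non-stationary spiking, or non-rectangular sampling windows.

## Numerical choices and degenerate inputs

Sholl requires a tree with positive radial extent; the hull requires
three non-collinear nodes; DSI and the von Mises fit require a nonzero
response. DRP requires the window to exceed twice the maximum radius per
dimension and at least one guard-zone reference. Validation of trees
returns a violation list (naming node ids) rather than raising, so
callers choose severity; file readers raise on malformed input with line
numbers. Probabilities, radii and counts are validated at parameter
construction. All Monte-Carlo routines (regularity baseline, simulated
units) take explicit seeds; derived seeds stay below 2³¹.

## Problem sizes used in the shipped checks

The test-suite and acceptance script run at desk scale, as the package's
own choice of default problem sizes: 50-seed arbor batches for
calibration and oracle comparisons, 99 seed pairs × 99 baseline
simulations for mosaic separation, 100 simulated units for parameter
recovery, 200 untuned units for the false-positive rate, 2000-point
patterns for the Poisson regularity baseline, and 2000 simulations for
type-I-error calibration of the t-test.

## Known limitations

Branch "level" follows the junction-counting convention and will differ
from software that increments level only at selected junction types.
The DRP effective radius depends mildly on bin width (5 µm default).
Regularity baselines condition on the observed point count (binomial,
not Poisson, baseline). The lamination compactness scalar is a package
definition, not a reimplementation of any published plugin's internal
statistic. Geodesic puncta distances go through the nearest tree *node*,
a ≤ one-segment-length approximation of the true projection point.
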