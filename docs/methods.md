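# Methods

This note documents the models, numerical choices and known limitations of
`wmhshape`: what each stage computes, why the defaults are what they are,
and what the synthetic data can and cannot say about real MRI.

## Geometry and masks

All imaging inputs are pairs of co-registered 3D binary masks (lateral
ventricles, WMH) sharing one grid.  Voxel centers sit at integer indices
mapped through the NIfTI affine; spacing is the column norm of the affine,
so anisotropic acquisitions (e.g. 0.86 × 0.86 × 3.00 mm FLAIR) are handled
in physical millimetres throughout.  Masks for one participant must share
shape and affine exactly; nothing is resampled.  Connected components use
26-connectivity by default — with 3 mm slices, in-plane diagonal
continuity is common and the permissive standard for lesion counting —
with 6-connectivity available.  WMH voxels inside the ventricle mask are
removed before typing (segmentation spill-in; a lesion's shape should not
include CSF space), and an optional brain-mask intersection is available as
a pre-filter for over-segmentation outside the brain.

## Lesion typing

Ventricle "inflation" is thresholding of the exact anisotropic Euclidean
distance transform, not iterated structuring elements, so 3 mm means 3 mm
in every direction regardless of slice thickness; voxels at exactly the
radius are inside (≤).  A component is **deep** when it has no voxel within
3 mm of the ventricles, otherwise **periventricular** when contained in the
10 mm zone and **confluent** when it extends beyond it.  Classification is
per connected component, a total function: every component gets exactly one
label, and the three typed sets partition the WMH mask.  Periventricular
and confluent lesions are merged for shape analysis (their spatial overlap
prevents separate treatment); participants with no lesion of a type are
excluded from that type's marker models, which is why the deep-marker
models can have a slightly smaller n than the cohort.

## Shape markers

Markers are computed per component in a local physical frame (index ×
spacing), making them invariant to rigid motion of the scanner frame and to
uniform rescaling (verified to 1e-6 relative in the tests).

**Surface area S** is the area of the 0.5-level marching-cubes isosurface.
Meshing the raw binary volume inherits the voxel staircase and
overestimates a smooth body's area by ~9% (voxel-face counting is worse,
up to ~1.5×, and is kept only as an explicit alternative estimator).  The
volume is therefore lightly Gaussian-smoothed before meshing, σ = 0.55
voxel: the smallest smoothing that brings a radius-10-voxel digitized ball
within ~2.4% of 4πr² while keeping the hull-area/surface-area ratio of the
same ball inside a sensible band around 1.  The smoothing is defined in
voxel units so the estimator stays scale invariant; components too small or
thin to retain a 0.5-crossing after smoothing fall back to the raw binary
isosurface.

**Convex hull.**  Hull *volume* V_H is the voxel-rasterized hull of voxel
centers: the number of voxel centers inside ConvexHull(centers), times the
voxel volume.  This choice is exact for axis-aligned cuboids, within 0.5%
of (4/3)πr³ for the radius-10 ball, and — because the rasterized hull is a
superset of the component — guarantees solidity = V/V_H ≤ 1.  The obvious
alternative, the polytope hull of voxel *corner* points (the true hull of
the voxel solid), overestimates a smooth body's hull volume by ~18% at
r = 10, which would bias solidity low for every round lesion; it is used
only as a fallback for degenerate center sets (fewer than four voxels,
coplanar/collinear centers), where it keeps V_H positive even for a single
voxel.  Hull *area* S_H is always the corner-point polytope area — exact
2(ab+bc+ca) for cuboids.  Mixing the two point sets is deliberate: each
quantity uses the representation that is exact for convex reference solids
of its own dimension.  A consequence worth knowing: smooth digitized bodies
have convexity S_H/S slightly above 1 (≈1.08 for the r = 10 ball), because
the corner hull bulges half a voxel beyond the isosurface.

**Concavity index** is (2 − convexity) + (1 − solidity): 1.0 for an ideal
convex body and strictly increasing as either ratio degrades.  All three
algebraic forms are named entries in a registry (`MARKER_FORMULAS`) so an
alternative combination can be swapped in without touching callers.

**Fractal dimension** is the least-squares slope of log N(s) against
log(1/s), where N(s) counts occupied boxes of side s voxels on a grid
anchored at the component's bounding-box corner, counted in index space.
The ladder is *fixed* at s ∈ {1, 2, 4} (truncated for components under
4 voxels across; below two usable scales the lesion is skipped and
counted).  Two measured facts drove this choice over a bounding-box-scaled
ladder: (a) boxes comparable to the whole object carry grid-quantization
noise — the count at s = 16 can jump 8 → 13 purely with how the bounding
box divides into 16-blocks — and (b) a ladder whose length depends on the
bounding box makes slopes incomparable between lesions of different
extent, producing systematic jumps whenever an object crosses a
power-of-two size.  With the fixed fine-scale ladder the closed forms are
exact whenever the box sizes divide the object side (solid cube → 3,
one-voxel plane → 2, line → 1) and the slope is comparable across lesions.
The slope is clamped to [0, 3].

**Eccentricity** is √(1 − λ₃/λ₁) of the second central moments of the
voxel solid: the covariance of voxel centers plus the moment of a single
voxel (spacing²/12 on the diagonal), i.e. voxels are treated as little
solid boxes.  The correction keeps λ₃ positive, so a one-voxel-wide rod
approaches but never reaches 1 and a single voxel is exactly 0.

**Aggregation** is the unweighted arithmetic mean over a participant's
lesions of each type — no volume weighting — with NaN where a type is
absent.  The minimum component size for shape scoring is 2 voxels;
sub-threshold components are skipped with a logged count.

## Synthetic phantoms

The phantom generator substitutes for MRI segmentations.  Ventricles are
two elongated digitized ellipsoid lobes (default semi-axes 4 × 22 × 5 mm,
16 mm apart) on a 96 × 96 × 48 grid at 1 × 1 × 2 mm — small enough for
fast tests; a 0.86 × 0.86 × 3.0 mm profile exists for clinical-spacing
fixtures.

A lesion is a star-convex body: radius along direction u is

    r(u) = r_ellipsoid(u) · max(1, 1 + κ·A·g(u)) · (1 + G·κ)

with g a band-limited zero-mean noise field on the sphere (12 random
cosine waves at angular frequency ~8, normalized to max |g| = 1, drawn
from the lesion seed), amplitude A = 0.35 and size coupling G = 0.7.
κ = 0 yields the exact digitized ellipsoid regardless of seed; any κ
produces one connected component by construction.  Two modelling choices
deserve explanation:

* *Outward-only protrusions.*  Zero-mean radial noise makes occupancy
  box-counting FD **fall** with roughness (it hollows the solid at fine
  scales), the opposite of the ordering the markers are meant to span.
  Clipping the perturbation at 1 turns irregularity into finger-like
  outgrowths — which is also how confluent lesions actually extend into
  the white matter — so volume and footprint grow with κ.
* *Size coupling.*  Irregular confluent WMH are systematically larger in
  vivo, and occupancy box-counting FD is partly size-sensitive; the mild
  global factor (1 + 0.7κ) reproduces that coupling and makes the FD
  ordering robust across seed sets rather than marginal.  It follows that
  κ is an *irregularity-and-extent* axis, not a pure-shape axis at fixed
  volume.

With these defaults, group medians over 20 seeds per κ ∈ {0, .2, .4, .6,
.8} order strictly — solidity and convexity decreasing, concavity index
and fractal dimension increasing — and the ordering was checked across
twelve disjoint 20-seed windows, not tuned to one.

Per-lesion ground truth records each lesion's min/max distance to the
ventricle surface and the implied type under the 3/10 mm rule, enabling
exact accuracy scoring of the typing stage.  Defaults the emulated study
does not pin down (lesion counts ~1 + Poisson, log-normal base radii,
uniform κ) are stated in the pipeline config, not asserted against
anything.

## Cohort simulation

The tabular simulator draws n = 2297 participants: age ~ N(74.5, 4.7²),
61% female, markers from the published summary distributions (solidity
log-normal with mean 0.19 and SD 0.12 — it is analysed on a log scale and
must stay positive; the other markers normal, truncated at 0.01), and
baseline WMH volume log-normal with mean 16.56 and SD 17.21 ml.

Outcomes follow the same models the analysis stage fits, on the same
standardized predictors (log-transform, z-score, inversion), so configured
effects are recoverable by construction.  WMH-volume change is linear with
intercept 5.76 ml, configurable slopes per SD of each marker (defaulting to
the reference estimates), small age/sex terms (+0.10 ml/yr, −0.30 ml for
women) and Gaussian noise (SD 6.5 ml); follow-up volume is baseline plus
that change, *not* clipped at zero — clipping would bias the configured
linear model, so a rare negative tail is accepted as the price of exact
recovery.  Binary new-lesion outcomes are logistic in the standardized
predictors with configurable ORs per SD; the intercept is solved by
bisection so the realized incidence matches the configured rate (13% new
microbleeds, etc.), and baseline flags are independent Bernoulli draws at
the baseline prevalences.  With several nonzero ORs configured at once the
single-predictor fits recover slightly attenuated values (omitted
independent covariates attenuate logistic marginals); the recovery tests
therefore use single-effect configurations.

## Statistical stage

Transforms: ln(100·x) for solidity and baseline WMH volume; z-scoring over
the analysis sample (sample SD, ddof = 1); sign-flip of the standardized
solidity, convexity and eccentricity.  The flip is applied in both model
families by default — the reference results are only coherent under that
reading — with a switch to restrict it to logistic models; a sign-flip
preserves |z| and p exactly and maps OR to 1/OR.  Linear models are OLS
with t-based intervals; logistic models are maximum-likelihood fits
(Newton, max 50 iterations, tol 1e-8) with Wald intervals exp(coef ±
1.96·SE).  Quasi-complete separation is flagged as an error, never
silently returned.  New-lesion models exclude participants positive at
baseline for that lesion type (at-risk population; configurable).  Missing
markers delete casewise per model, so each marker family reports its own
n.  No multiple-testing adjustment is applied; p < 0.05 is the
significance convention, with stars at 0.05/0.01/0.001.

## Problem sizes

Defaults were chosen so the full test suite and the acceptance script each
run in well under a minute of compute per stage: phantoms on the
96 × 96 × 48 grid, κ-ladder lesions with 10 mm base radius on a 44³ local
grid (20 seeds × 5 κ ≈ 15 s), coverage checks at n = 2300 × 100
replicates, and the permutation null at n = 2000 × 400 permutations.

## Limitations

* The phantoms emulate mask geometry only: no FLAIR intensities, scanner
  noise, registration error, or anatomically realistic ventricle shape.
  Passing tests demonstrate correctness of the geometry and statistics on
  controlled inputs, not segmentation robustness on real MRI.
* Box-counting FD on the fixed fine ladder is a finite-size slope, not an
  asymptotic dimension; its absolute values (≈2.6 for 10 mm-radius
  phantom lesions, ≈1.7 for small clinical lesions) depend on lesion size
  relative to the voxel grid and should be compared only within a fixed
  acquisition geometry.
* Simulated markers are drawn independently across participants and
  markers; real shape markers are strongly inter-correlated, so the
  default grid overstates the independent information per marker.
* Convexity slightly above 1 for smooth bodies is a property of the mixed
  hull/isosurface estimator pair, consistent with population means
  slightly above 1 on real data, but means convexity is not bounded by 1.
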