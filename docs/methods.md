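# Methods

This note documents the models, algorithms and design choices in hepavess:
what each component assumes, which parameters matter, and what the phantom
experiments do and do not demonstrate.

## Coordinate and grid conventions

Arrays are indexed `(x, y, z)` with `z` the across-plane (slice) axis;
voxel indices are 0-based and `world = origin + index · spacing` in mm.
All tolerances, scales and gap lengths are physical (mm), never voxels,
because clinical grids are anisotropic — in-plane pixels of ~0.7–1 mm
against slice thicknesses up to ~2 mm.  Resampling to a target spacing
produces `ceil(extent / spacing)` voxels per axis, so content is never
truncated; masks are resampled with nearest-neighbour interpolation
(order 0), intensities and probabilities with linear (order 1).

## Synthetic phantoms

The generator emulates the structures relevant to hepatic-artery (HA)
segmentation in an arterial-phase abdominal CT:

* a vertical aorta (default radius 9 mm) with a lateral celiac trunk
  (4 mm) splitting into left/right hepatic arteries and recursively
  branching for `depth` generations (default 3) with radius taper 0.7 per
  generation — deepest branches 4·0.7³ ≈ 1.37 mm, matching the small
  calibers that make the HA hard;
* a convex ellipsoidal liver region enclosing all branch nodes beyond the
  first branching (convexity guarantees intrahepatic segments lie inside);
* optional confounders, disjoint from the vessel mask by construction: a
  bright tube parallel to a hepatic branch (vein), a bright ellipsoid
  abutting the aorta (kidney), an isolated bright speck (gallstone);
* an anatomical-variant mode rerouting one first-generation branch to
  originate directly at the celiac trunk, as seen in roughly a third of
  patients; benchmark sets enable it for every third case.

Vessels are straight swept tubes (voxel inside iff its centre is within
the linearly interpolated local radius of a segment — a capsule, which
keeps the analytic `πr²L + 4/3·πr³` volume oracle available).  The image
is a constant parenchyma level (60 HU) plus vessel contrast (+200 HU),
Gaussian-blurred to a configurable FWHM (default 1 mm) with seeded
additive Gaussian noise (default σ = 10 HU; the "clean" pipeline
experiments use σ = 2).  The default grid is 128×128×96 at (1, 1, 2) mm;
tests and the acceptance script use 64×64×48 and 48×48×32 at the same
spacing to keep single-CPU runtimes in seconds to minutes.

What the phantoms do **not** model: beam hardening, contrast kinetics,
textured parenchyma, curved vessels (beyond optional sinusoidal
perturbation), organ boundaries with intensity contrast.  Passing on
phantoms therefore demonstrates algorithmic correctness (geometry,
connectivity, cost logic, metric arithmetic), not clinical performance.

## Classical vesselness pipeline

The traditional comparator chain runs entirely on a fixed isotropic
(0.5 mm)³ working grid:

1. **Multi-scale vesselness.**  Frangi's bright-tube measure from the
   γ-normalized Hessian (γ = 2) at scales {0.5, 1, 2, 3, 4} mm,
   α = β = 0.5, structure sensitivity `c` set per scale to half the
   maximum Frobenius norm of the Hessian.  The response is the per-voxel
   maximum over scales; the direction field is the eigenvector of the
   smallest-magnitude eigenvalue at the winning scale.  Two numerical
   details: second-derivative Gaussian kernels at sub-voxel σ leak a DC
   component when truncated, which is measured on an impulse and
   subtracted (a constant volume then yields an exactly zero response);
   and a small relative floor on `c` guards against float32 residue.
2. **Bayesian classification.**  Two univariate Gaussians on the response
   with size-proportional priors; a voxel is vessel iff its posterior
   exceeds 0.5.  The vessel class is estimated from the bright
   contrast-enhanced voxels (intensity ≥ 150 HU-like) united with a 5 mm
   sphere around the seed; the background class from a seeded uniform
   random sample (20 000 voxels) of the remainder.  Estimating the vessel
   class from the seed sphere alone does not work: the seed sits in the
   aorta, whose *interior* has almost no tubular response, and a
   background sample restricted to below-median response has near-zero
   variance — both degenerate the discriminant into labelling half the
   volume vessel.
3. **Component filter.**  26-connected components of the classification
   smaller than 2 mm³ are discarded as noise (the seed component is always
   kept).
4. **Directional gap filling.**  Line extensions of up to 3 mm grow along
   ± the local vessel direction, but only across faces where the direction
   exits the mask, and an extension is kept only if it reaches a
   *different* fragment.  Unconditional per-voxel line dilation grows
   1-voxel whiskers at every vessel ending whose skeletons alone cost
   0.3–0.5 clPrecision on an otherwise perfect segmentation; restricting
   to bridging extensions preserves the gap-filling purpose (the operator
   remains extensive) without the artifacts.
5. **Connectivity reconstruction.**  Starting from the seed's component,
   fragments whose closest physical distance is ≤ `max_gap` (5 mm) are
   iteratively bridged by straight voxel segments; farther fragments are
   discarded.  The output is resampled back to the input grid and
   reconnected once more there, since order-0 downsampling can skip
   1-voxel bridges.

The seed is found automatically as the largest-radius skeleton voxel of
the thresholded bright structures — in practice a point inside the aorta —
with a manual seed as fallback; an all-dark volume raises a distinct
seed-failure error.  The pipeline is intentionally intensity-driven and
*should* leak onto other enhancing structures: on phantoms with the
parallel-vein confounder, part of the vein joins the output and
clPrecision drops — the characteristic weakness of this method family.

## Cost-based tree connection

Learned probability maps are combined (voxelwise maximum of the fine map
and the linearly-resampled coarse map), thresholded at 0.5, and every
26-connected component is connected to a root or pruned.  The root is the
skeleton voxel with the largest distance-transform radius in the coarse
(large-vessel) output — ties broken by smallest linear index — falling
back to the joined map when no coarse map is given.  Edge weights on the
full voxel grid are `(1 − (p(u)+p(v))/2) · step_mm`, clipped to be
non-negative; scaling by the physical step makes costs comparable across
resolutions, and letting paths traverse voxels *outside* the binary mask
is precisely what allows gap bridging.  Shortest paths use Dijkstra
(scipy's csgraph) from the root component as a multi-source; each
component's cheapest entry point defines its connection cost, its
predecessor chain the bridging voxels.  Components above `max_cost` are
removed; the kept set grows monotonically with the budget.  There is no
endorsed default budget — the trunk-gap experiment shows it is
case-critical: with a probability gap between trunk and intrahepatic
split, a small budget prunes every liver branch (clRecall ≈ 0) and a
larger budget restores them (clRecall ≈ 1).

## Anisotropic U-Net

A 5-level U-Net in which every 3D convolution is decomposed into a 3×3
in-plane convolution followed (from level 3) by a 3-tap across-plane
convolution; levels 1–2 contain no across-plane convolutions and pool
in-plane only (2×2×1), levels 3–4 pool 2×2×2.  The across-plane receptive
field is therefore smaller than the in-plane one by construction (78 vs 18
voxels for the default layer stack).  Convolutions use edge padding, so a
constant input produces an exactly constant output and tiled prediction
shows no seams on flat regions.  The implementation is explicit numpy
forward/backward with Adam — sized for phantom micro-scale (channels
(8, 16, 32, 64, 128) by default, (4, 8, 16, 32, 64) in the experiments;
patches 32×32×8; minutes on one CPU), not for clinical training.

The loss is the weighted soft-Dice complement
`1 − (2·Σw·p·t + ε)/(Σw·p + Σw·t + ε)` with per-patch inverse class
frequency weights.  Optimizing Dice alone at this scale is unstable: the
all-foreground corner is a local optimum (loss exactly 1/3 under balanced
weights) where the saturated sigmoid kills the gradient, and roughly half
of the random seeds collapsed into it.  Training therefore adds an
auxiliary weighted cross-entropy term (weight 0.5) whose logit gradient
`w·(p − t)` survives saturation — standard compound-loss practice; the
reported per-epoch loss remains the weighted Dice itself.  The final-layer
bias is initialized to −2 so an untrained model predicts background, the
appropriate prior for rare foreground.  Whole-volume prediction tiles the
resampled volume with overlapping patches (overlap 8) and averages.

Training on 8 phantoms (7 train / 1 holdout) drops the epoch Dice loss
from ~0.2–0.5 to ~0.02–0.13 and takes the holdout clRecall of the
thresholded prediction from ~0 (untrained) to ~1.

## Centerline metrics

Both masks are restricted to the liver, skeletonized by 3D thinning, and
scored against the other mask dilated by the tolerance (2 mm default).
Dilation uses the exact Euclidean distance transform with the grid spacing
as sampling, i.e. an ellipsoidal structuring element in voxel space and a
true ball in physical space (at unit spacing the 2 mm ball contains 33
lattice points).  Restricting *before* skeletonizing makes the scores
invariant to arbitrary changes outside the liver.  An empty prediction
leaves clPrecision *undefined* (reported as `None`) rather than 0 —
producing nothing is a different failure from producing something wrong —
while clRecall is 0 by contract and clF1 0; an empty restricted reference
excludes the case.  The Wilcoxon signed-rank test drops zero differences,
averages tied ranks, uses `min(W+, W−)`, enumerates the exact null for
n ≤ 12 and uses the tie-corrected normal approximation with continuity
correction above.

## Rating analytics

Ratings are ordinal: image quality − ◦ + encoded −1…+1, segmentation
quality −− … ++ encoded −2…+2 (the encodings are exposed, since
correlation analyses depend on them), usability boolean.  Missing results
are first-class records that reduce the per-method n.  Percentages round
half away from zero to two decimals.  Medians use the lower median for
even samples so the reported value is always a scale member.  Intra-reader
consistency counts cases whose image quality was rated identically across
every available presentation; the accompanying n counts cases rated under
all methods.  `demo_rating_table()` builds a deterministic 36-case table
with prescribed aggregate counts (one method missing one case) as the
worked example for all of this arithmetic.

## Problem sizes and determinism

Every stochastic component (phantom noise, benchmark case seeds, training
patch sampling, background sampling in the classifier) is driven by
explicit integer seeds; identical seeds give bit-identical phantoms and
reproducible training curves.  The test suite and the acceptance script
use 48³–64³-scale phantoms, 12-case benchmarks, 8-case training sets and
100 random 6³ grids for the shortest-path oracle — sizes chosen so the
full suite runs on a single CPU in minutes while still exercising every
code path end-to-end.

## Known limitations

* The phantom's parenchyma is homogeneous; classifier separability is
  easier than in real CT, where texture and partial-volume effects blur
  the response distributions.
* The Bayesian classifier is univariate Gaussian on the vesselness
  response only; real pipelines may use richer features.
* The U-Net is micro-scale; its results say nothing about clinical-scale
  accuracy, only that architecture, loss and training machinery work.
* `connect_to_root` builds the full-grid graph in memory; for large fine
  grids (≳10⁷ voxels) memory, not time, is the binding constraint.
* The tree generator produces straight branches with fixed taper; radius
  anisotropy, stenoses and vessel wall effects are out of scope.
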