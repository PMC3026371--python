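# Methods

This note records the models implemented in `dermoseg`, the parameter
choices that matter, what the synthetic phantoms do and do not emulate, and
the numerical decisions taken where the design was genuinely open.

## High-boost sharpening

The filter is the linear combination g = A·f − B·S(f) − C·∇²f, where S is
the sum of directional derivatives along (±1, ±1) and the Laplacian uses the
standard 5-point stencil, all with two-node forward differences
f(x+d) − f(x). Expanding on a 3×3 support gives center A+4B+4C, the four
edge-adjacent entries −C, the four diagonal entries −B, and entry sum A.
The output is correlated per channel with replicate border padding, rounded
and clamped to [0, 255].

Behavior under the default (A, B, C) = (6, 0, 1): any flat region with gray
level above ⌈255/6⌉ = 43 saturates to white, so typical skin background
becomes uniformly 255 and moderate-contrast artifacts are erased; a strong
step edge survives as a one-pixel valley on its dark side (value
10·f_dark − Σcross, e.g. ≈100 for a 40/180 edge). The active contour's
freeze test reads exactly this valley. A = 0 instead yields the dark
background / thin bright boundary regime; larger masks (wider stencils) are
out of scope.

## Intermeans thresholding

Starting from T₀ = ⌊(j+k)/2⌋ over the occupied gray range [j, k], iterate
T ← ⌊(μ₁+μ₂)/2⌋ with count-weighted class means until the threshold is a
fixed point (floor, not round-half-up, keeps the update integer-valued and
deterministic). T is an integer in [0, 255] and the update is a
monotone-bounded fixed-point iteration, so 256 iterations is a safe hard
cap; in practice convergence takes a handful. If one class empties (a
single-level histogram) the current T is returned with `mu2 = None`. The
positive (lesion) class is the one with the lower mean — which, since
μ₁ ≤ T < μ₂ whenever both classes are non-empty, is always the ≤ T class:
dark lesion on light skin.

## Active contour

The contour is the exact first-harmonic solution of the linear geometric
heat flow r_t = r_ss on the parameter circle:
r(s, t) = c + e^{−t}(a₀ cos s, b₀ sin s). Time is dimensionless; the curve
is an ellipse inscribed in the image (margin 2 px, so it starts in
background by construction) that shrinks strictly monotonically toward the
center. Sample density is one point per pixel of initial arc,
N = ⌈P⌉ with P the Ramanujan perimeter approximation.

Per-point boundary condition: at each step the closed-form candidate at
t + Δt is computed for every unfrozen point; if t + Δt > 0.001 (grace time)
and the image intensity at the candidate departs from the background
reference by more than τ, the point freezes at its current (time-t)
position and never moves again; otherwise it moves to the candidate.
Numerical choices made here, with reasons:

- **Background reference**: median of the image sampled along the initial
  ellipse. The initial contour lies in background by construction, and the
  median is robust to a few artifacts crossing it. On the boost-filtered
  image this is 255 (saturated background), so the freeze test reduces to
  "candidate intensity below 255 − τ", i.e. the point has reached an edge
  valley.
- **τ = 30 gray levels**: about 3σ of the post-filter noise seen on
  *saturated* regions (whose clean margin is huge), while the 40/180 edge
  valley (≈100) sits ~125 levels below the threshold — a comfortable
  detection margin on both sides.
- **Bilinear sampling** at the continuous candidate coordinates. The border
  evidence after filtering is a one-pixel-wide valley; sampling the nearest
  pixel lets a shrinking point occasionally hop diagonally across the
  valley without ever reading it and collapse to the center. Interpolated
  sampling registers any crossing that passes within the valley pixels'
  support. Out-of-image candidates are clamped to the border pixel.
- **Adaptive time step** Δt = min(0.01, 0.5/max(a₀, b₀)) by default: the
  per-step travel of a point is (current amplitude)·Δt, so this caps travel
  at about half a pixel and the freeze test cannot step over the evidence.
  A user-supplied Δt overrides the adaptation (the step scales with image
  size, as it should: larger images need finer relative steps).
- **Freeze pins the pre-step position**, reading the boundary condition
  literally (the value at t + Δt is set equal to the value at t). Combined
  with the travel cap this biases the frozen border outward by under a
  pixel.
- Evolution stops when every point is frozen or the unfrozen amplitude
  e^{−t}·max(a₀, b₀) falls below ε = 0.5 px, giving the hard step bound
  ⌈ln(max(a₀, b₀)/ε)/Δt⌉. If no point froze at all (uniform image), the
  result mask is empty rather than a rasterized ε-sized speck.

The final mask is the even-odd (crossing-number) rasterization of the point
polygon over pixel centers, half-open in both axes; self-intersecting
polygons (collapsed spikes) are filled by parity with a warning.

## Boundary-driven clustering

`run_bd_dbscan` is classic DBSCAN (inclusive Euclidean distance ≤ R on
pixel centers, minimum population MP counting the point itself) augmented
with a per-cluster polygonal boundary used solely to prune queries:

- The boundary starts as the convex hull of the first accepted query and
  grows by unioning each subsequent accepted query's hull (robust boolean
  union with hole support via shapely/GEOS). Because a hull merged into the
  region is the hull of points all within R of its query point — a convex
  constraint — every dataset point inside the filled region is already a
  labeled member of the cluster.
- A popped member is **skipped** iff it lies inside the filled region and
  its distance to every boundary curve (outer and holes) is at least R:
  then its closed R-ball is covered, its query could return only existing
  members, and skipping is lossless. This is the minimal criterion under
  which pruning provably cannot change the result; the test suite
  re-verifies every skip with an independent geometric predicate (crossing
  counts and segment distances in numpy, separate from the shapely
  predicates that made the decision).
- Seeds are processed **depth-first** (LIFO over discovery order, with the
  deterministic lexicographic (y, x) order inside each query result).
  Breadth-first processing was measured to defeat the pruning entirely: the
  hull frontier advances R per generation, so every member pops exactly
  when the boundary is marginally under R away and no query is ever
  skipped. Depth-first lets the region close around interior members
  before they pop; on a 40×40 solid block with R = 5, MP = 60 this prunes
  843 of 1600 queries. Membership of a DBSCAN cluster is independent of
  expansion order, so the partition is unaffected — the suite asserts exact
  label equality with a classic-DBSCAN reference on randomized blob, ring
  and noise mixtures, and the core-point partition additionally agrees with
  scikit-learn's DBSCAN.
- Degenerate (collinear) hulls are kept as zero-area geometries whose every
  point counts as boundary, so they never enable a skip; if a union ever
  splinters numerically, only the polygonal part is retained, which can
  only make pruning more conservative.
- Holes (the donut case) are preserved by the union algebra
  C* = (P₁ ∪ T) − (P₂ ∪ … ∪ Pᵢ): a member near a hole wall remains
  leading, so rings cluster correctly; covered holes are absorbed.

Defaults R = 5, MP = 60 are the dermoscopy settings; MP ≈ 75% of the
R-disc's 81 lattice points demands near-solid local density. The final
lesion mask is the largest cluster (ties broken toward the smaller id).
`BoundaryDrivenDBSCAN` wraps this as a scikit-learn
`ClusterMixin`/`BaseEstimator` (noise −1, labels 0-based).

## Evaluation metrics

Border error is computed both as pixelwise XOR over the manual area and as
(FP+FN)/(TP+FN); the implementation asserts their equality on every call.
An empty manual mask raises instead of defaulting 0/0 — degenerate ground
truth should fail loudly. The metric is asymmetric (the denominator is the
manual area) and can exceed 1. Batch evaluation emits one row per image
with min/max/mean/stdev summary rows.

## Synthetic phantoms

`make_phantom` emulates the features of dermoscopy images the two methods
actually interact with: a dark, harmonically perturbed elliptical lesion
(radial boundary 1 + Σ aₖ cos(kθ + φₖ), default orders 2/3/5 with relative
amplitudes 0.04/0.06/0.03) on a lighter background, per-channel Gaussian
noise, thin hair polylines and bright bubble discs. Defaults: 600×400 px
(the lower end of typical dermoscopy acquisitions), lesion lightness 40 vs
background 180 — luminance contrast 140, chosen so that the background
saturates under the (6, 0, 1) boost while the lesion-edge valley stays far
below the freeze threshold, and plausible for a pigmented lesion on light
skin — noise σ = 10, 5 hairs, 5 bubbles. The ground truth is the exact
analytic lesion region; artifacts and noise never alter it.

Artifact design: default hairs are light brown (lightness ≈ 107) — clearly
visible in the raw image, but erasable by the boost filter, which is the
filter's purpose; their filtered response stays ≈3σ above the freeze
threshold. Bubbles may fall anywhere, including over the lesion, where they
punch small false-negative holes in the thresholding pipeline (this is what
keeps BD-DBSCAN's recall below its precision). The `hairy` preset instead
uses near-black hairs that survive the filter and provoke the documented
contour-spike failure mode; it exists as a behavioral stress case, not a
accuracy benchmark. What the phantoms do **not** model: skin texture,
illumination gradients, dermoscopic gel, color calibration, and fuzzy
(gradual) lesion borders — the phantom edge is a hard two-level step.
Passing accuracy numbers therefore demonstrate correctness of the
machinery under controlled contrast and noise, not clinical performance.

`make_point_cloud` builds labeled lattice clouds (solid discs with optional
subsampling, annuli for the donut case, uniform noise) for the clustering
tests; overlapping discs merge their intended labels.

## Problem sizes and determinism

The standard study run by `scripts/acceptance.py` is 20 noisy phantoms plus
one clean phantom, with classic DBSCAN replayed on five of them for the
query-savings figure; the equivalence suite uses 100+ randomized clouds of
up to ~2000 points across R ∈ {2, 3, 5} and MP ∈ {4, 10, 60}. Both
pipelines are fully deterministic given their inputs; all synthetic
randomness flows through explicit integer seeds, and the acceptance script
derives every seed from its `--seed` argument.

## Known limitations

- The contour cannot recover concavities deeper than its shrink paths
  allow, and freezes permanently on the first evidence it meets: a single
  dark artifact in its path leaves a spike (see the `hairy` preset). A
  noise-robust boundary condition is the natural next step.
- The contour freeze depends on the background saturating under the boost
  mask; very dark skin backgrounds (lightness < ~43 after tinting) would
  need a different (A, B, C).
- BD-DBSCAN inherits thresholding errors: anything the intermeans split
  mislabels (bubbles over the lesion, very light lesion zones) is invisible
  to the clustering stage.
- Pruning soundness relies on exact geometric predicates; the
  implementation delegates to GEOS and re-merges numerical splinters, but a
  pathological degeneracy would surface as a geometry error rather than a
  wrong partition.
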