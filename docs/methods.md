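# Methods

## The volume-based gap fraction

The crown is modelled as a porous medium. Vegetative elements (leaf blades
and branch segments) are the solid matrix; the remaining crown space is
pore. The volume-based gap fraction is the void fraction

GF_vol = 1 − (Σ_t V_leaf_t + Σ_u V_branch_u) / V_canopy,

where `V_leaf_t` is the hexagonal-prism volume of leaf *t*, `V_branch_u`
the cylinder volume of branch segment *u*, and `V_canopy` the alpha-shape
volume of the vegetative points above the lowest branch. Unlike
hemispherical-photo or optical-transmission estimators, the quantity does
not depend on an observer position or a beam direction; it does depend on
how well each element's volume is reconstructed, which is what the
synthetic benchmark measures.

A reported GF_vol outside [0, 1] (prisms overlapping beyond the crown, or
a hull smaller than its contents) is returned as computed with a warning
rather than clamped, so pathological geometry stays visible.

## Pipeline stages and their assumptions

### Wood/leaf classification

Per-point features come from the covariance of the k = 20 nearest
neighbours plus the point: linearity (λ1−λ2)/λ1, planarity (λ2−λ3)/λ1,
scattering λ3/λ1 (descending eigenvalues; degenerate neighbourhoods map to
(0, 0, 1)). The default threshold rule labels a point wood iff linearity
> 0.8. The 0.8 cut was chosen from the geometry of the two regimes: a
neighbourhood that wraps a slender twig is a tube with linearity ≈ 0.9,
while lamina patches stay below ≈ 0.75 even at the rim, where the
half-disk neighbourhood is itself fairly elongated (linearity ≈ 0.72). A
lower cut (e.g. 0.6) labels entire leaf margins as wood. The rule assumes
branches are slender relative to the neighbourhood scale ~ √(k/πρ) at
point density ρ; thick trunks at high density present locally planar bark
surfaces and need the trainable Gaussian/SVM classifiers (also provided)
plus labelled examples. Ambiguity defaults to leaf: leaf volume is summed
directly, while wood volume comes from cylinder fits that tolerate missing
points.

### Leaf-surface centre detection

A point is a candidate leaf centre iff, within a spherical neighbourhood of
radius R = 0.75 × (average half leaf width) (species prior, not estimated
from the data):

1. the mean absolute distance to the least-squares plane *through the
   point* is < threshold1 (default 0.2 R);
2. the mean angle between its robust normal and its neighbours' normals is
   < threshold2 (default 15°);
3. the index of dispersion σ′ of the 40-cell angular occupancy is
   ≤ threshold3 (default 2.0).

The robust normal is an iteratively reweighted smallest-eigenvector
estimate with Gaussian weights exp(−(wᵀn)²/h²), h = median |wᵀn₀|, at most
20 iterations, convergence at 1e-4 rad. A direct minimisation of
Σ (wᵀn)² exp(−(wᵀn)²) is ill-posed (the objective vanishes as residuals
grow), so the reweighting scheme realises its intent — down-weighting
off-plane offsets — in a well-posed form.

For σ′, the great-circle disk is split into 8 sectors × 5 equal-area
annuli (boundary radii R√(d/5)); σ′ = [Σ(num_d − μ)²/40]/μ. This is a
variance-to-mean ratio (≈ 1 for uniform coverage, large for partial
coverage); a square-root variant is available behind a config flag but off
by default. The statistic only discriminates when the mean per-cell count
is ≳ 2–4, hence `min_neighbors` = 40 — also the minimum per-leaf point
count the scanning protocol is assumed to deliver. With ~15-point
neighbourhoods, thin point strips (stray twig chains) routinely slip under
threshold3.

Candidates form dense bands along each lamina's interior, so suppression
is *chained*: candidates within R/2 of each other are linked into
connected components and only the lowest-σ′ member of each component
survives. Greedy non-maximum suppression would instead leave a survivor
every R/2 along the band — several seeds per leaf — and systematically
oversegment.

### Instance growing

Seeds grow by multi-source Dijkstra over the symmetric kNN graph (k = 10),
with two caps: geodesic distance ≤ 2 × average leaf length, and edge
length ≤ 3 × mean nearest-neighbour spacing. The edge cap keeps sparse
off-surface chains (misclassified twig points) from being pulled into a
lamina's basin — without it the extreme-projection thickness of affected
instances inflates several-fold. Unreached points go to DBSCAN
(eps = 4 × mean spacing, minPts = 10); clusters of ≥ `min_leaf_points`
(40) become new instances, the rest is noise (−1). The eps factor is 4
rather than 2 because a 2-spacing ball on a surface-sampled cloud holds
only ~3–5 points — below minPts, which would label everything noise.

### Per-leaf hexagonal prism

Each instance is smoothed by moving least squares (local degree-2
polynomial in the tangent frame, Gaussian weights of bandwidth
support/2, support = leaf width / 4; degree-1 fallback below 6 neighbours)
— the step that removes wind-ghost points. Then:

* midrib endpoints = farthest point pair (exact scan to M = 5000, convex
  hull beyond; petiole = lower-z endpoint, ties lexicographic);
* n_slices − 1 = 20 uniform bands along the midrib; per band, the extreme
  points along e2 = normal × axis give raw left/right edges;
* two independent cubics v(u), w(u) per side, solved via the 4×4 normal
  equations in the leaf-local frame (the global-coordinate
  parameterisation degenerates when the midrib is perpendicular to the
  chosen axis; the local frame is equivalent when aligned and robust
  otherwise). The abscissa is shifted/scaled internally for conditioning;
* hexagon = petiole tip, left edges at 1-based positions round((n−1)/4)
  and round(3(n−1)/4) (round-half-up), apex, and the mirrored right picks;
* equivalent thickness = extent of the fitted points along the covariance
  normal; volume = planar hexagon area × thickness. The six vertices are
  projected to their best-fit plane first (a prism base should be planar;
  off-plane extent is already captured by the thickness). The area is the
  shoelace value, which equals the upper-triangle + trapezoid +
  lower-triangle decomposition for every simple hexagon of this ordering;
  self-intersecting bases are rejected.

Instances below 40 points, or failing hexagon construction, fall back to
the covariance-aligned bounding-box volume (`fallback_bbox`); below 3
points they are `rejected` with zero volume.

Exact (1e-9 relative) rigid-motion invariance of thickness and volume
holds for vertical-axis rotations and translations; a tilted rotation can
swap which midrib endpoint counts as the petiole (a lower-z convention),
which relabels edge bands and perturbs the hexagon slightly, so only
percent-level invariance is possible there.

### Branch cylinders

Wood points are linked into a proximity graph (k = 10, edge cap 5 × mean
spacing) with a direction-coherence gate: points whose wider (k = 30)
neighbourhood is slender (linearity > 0.7) only link to neighbours with
aligned principal directions (< 35°). This makes branch networks fall
apart into per-twig chains at junctions; without it, several twigs
radiating from one junction stay connected and can jointly mimic a large
cylinder surface that a least-squares fit accepts with small residuals.
Components are cut into runs of ≤ `segment_length` (default 0.05 m) along
their principal axes, re-splitting runs that remain disconnected;
fragments under 20 points fold into the adjacent segment. Each segment
gets a least-squares cylinder (axis from the principal component, then
Levenberg–Marquardt on point-to-axis distance; fits whose radius exceeds
1.5 × the transverse point spread are rejected as the under-constrained
"huge distant cylinder" solution, falling back to the PCA axis + median
radius, flagged). The 0.05 m default keeps junction-spanning runs short:
the wood-volume error of a branching fixture scales roughly linearly with
run length (≈ 6% at 0.05 m vs ≈ 18% at 0.1 m).

### Crown volume

Vegetative points above the crown base enter a 3D alpha shape: Delaunay
tetrahedra with circumradius ≤ α, α = ∞ giving exactly the convex hull
(the default, matching the hull-like crown envelopes of broadleaf trees;
finite α serves concave crowns). The automatic crown base is the lowest
wood point more than twice the trunk radius from the trunk axis, with the
axis and radius estimated from the lowest 20% of wood points (radius as
their 98th-percentile radial distance, so measurement noise on the trunk
surface does not masquerade as a low branch).

## Baselines

* **Hemispherical photo**: points above the observer are mapped by
  zenith/azimuth to a Lambert azimuthal image (equal-area by default;
  equal-angle via config) and splatted as disks of angular radius 0.15°;
  GF per zenith ring = sky pixels / ring pixels; the 57.3° convention is
  the ring [52.3°, 62.3°].
* **Voxel occupancy**: axis-aligned grid (default 0.1 m) anchored at the
  cloud minimum; GF = (V_crown − V_occupied)/V_crown, clamped at 0 with a
  warning.
* **Beer–Lambert**: P(θ) = exp(−G(θ)·Ω·LAI/cos θ), exact evaluation with
  validated parameters (G > 0, 0 < Ω ≤ 1, LAI ≥ 0, θ < 90°). A full
  zenith × azimuth transmission matrix via per-beam ray tracing is out of
  scope; the voxel GF plus this closed form cover the comparison.

## The synthetic benchmark

`SyntheticTreeSpec` defaults define the package's study conditions: a
~1 m sapling — 0.5 m trunk of 0.8 mm radius, three levels of three
tapering twigs (radius taper 0.7, branching angles 35–55°) inside a
spheroidal envelope — carrying 50 elliptic leaves (length 3–4.2 cm, width
1.8–2.6 cm, curl 1–5 mm, droop 5–20°) on 1 cm petiole stand-offs,
alternating sides of their twig, midribs fanning radially outward. Surfaces
are sampled at 5×10⁵ points/m² with 0.5 mm Gaussian noise — ~20,000 points
per tree, with every leaf carrying well over the 40-point minimum. These
sizes keep a five-tree benchmark within a few CPU-minutes while preserving
the scale ratios that matter (neighbourhood radius ≪ leaf width; twig
radius below the slenderness scale of the eigen-features; per-cell counts
of σ′ ≳ 3).

Ground truth is analytic: per-leaf volumes apply the *same* hexagon-prism
definitions to a dense noiseless, sampling-independent surface grid (so
pipeline-vs-truth error isolates segmentation/fitting, not model
mismatch); wood volume is the sum of generating cylinder volumes; crown
volume is the hull of the noiseless geometry above the trunk top. Doubling
the sampling density leaves all truth values unchanged.

What the generator does **not** emulate: occlusion and beam divergence
(sparse-data robustness is tested by lowering density instead),
registration artefacts from multiple scans, wind ghost points beyond
i.i.d. noise, petiole/vein geometry, compound leaflets, and bark texture.
Passing the benchmark therefore demonstrates the geometric machinery under
clean acquisition; field scans add occlusion-driven under-segmentation
that the published experiments handle by scan-protocol choices, not by the
algorithms tested here.

On these conditions the pipeline recovers GF_vol to within 0.01 of truth
per tree (typically ≤ 0.007). The dominant residual is leaf-volume
overestimation from imperfect instances: an instance containing points of
two touching leaves, or a few stray twig points, inflates the
extreme-projection thickness. Detected instance counts fluctuate ±15% per
tree (merges of touching leaves vs junction-blob seeds) while their mean
across trees is unbiased; the count property is therefore asserted on the
across-tree mean, with a ±20% per-tree sanity band. Because GF_vol ≈ 1 −
(element volume)/(crown volume) and elements occupy well under 1% of this
sparse crown, GF recovery is considerably more forgiving than per-leaf
volume recovery, which is tracked separately: across a curl 0–2 cm ×
droop 0–30° grid at 2×10⁵ points/m² and 0.5 mm noise, the median absolute
relative volume error is ≈ 12% (inflation is worst for near-flat leaves
whose true thickness is comparable to the post-smoothing noise floor).

## Numerical conventions

* Normals carry a fixed sign (z ≥ 0; ties broken on y, then x); angular
  tests use |n·n′| and are orientation-free.
* Degenerate neighbourhoods (collinear) raise; exactly planar
  neighbourhoods short-circuit the IRLS (weights are irrelevant at zero
  residual).
* Voxel indices floor after adding 1e-9 voxel so points an ulp below a
  boundary land inside it.
* All randomness flows through `numpy.random.default_rng` seeds carried in
  the specs; identical inputs + config produce byte-identical JSON
  reports.
* Units are metres throughout; `unit_scale` rescales other inputs at load.

## Known limitations

* The linearity-threshold classifier has no notion of thick trunks at
  high density (locally planar bark); use the trainable classifiers there.
* Touching or interpenetrating leaves merge or split instances; no
  post-hoc instance-level split/merge heuristics are applied.
* The fan (ginkgo-like) planform uses the same hexagon index rule as the
  elliptic planform; the asymmetric larger-upper/smaller-lower triangle
  split falls out of the edge geometry rather than a dedicated rule.
* LAS/LAZ input and multi-scan registration are not supported; leaf-area
  index retrieval is out of scope.
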