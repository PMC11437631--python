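# Methods

## From mask to centerline graph

Input is one binary raster per vessel class (any nonzero pixel is
vessel) and a disc annotation `{"center": [row, col], "diameter": D}`
in pixels. Coordinates are 0-based `(row, col)`; node positions are
continuous; angles are reported in degrees.

Thinning uses the standard morphological skeletonization of
scikit-image, which preserves 8-connectivity and is idempotent on
1-pixel structures. Skeleton pixels with ≠2 eight-neighbours become
node pixels: adjacent junction pixels (≥3 neighbours) are merged into
one node at their centroid, since thinning regularly produces 2×2
junction blocks for what is anatomically a single point; endpoints are
singleton nodes. Edges trace the maximal degree-2 pixel paths between
node pixels, so every skeleton pixel is accounted for exactly once by
a node cluster or an edge interior (a property the test suite
asserts). Arc length is the polyline length of the traced path
(1 per axial step, √2 per diagonal).

Thinning artifacts are cleaned to a fixpoint before measurement:

* terminal spurs shorter than `max(5 px, 1.5 × parent diameter)` are
  removed (both constants configurable); the adaptive part reflects
  that spur artifacts scale with vessel width;
* tiny self-loops and short parallel duplicate edges — holes punched
  into a junction bulge by thinning — are dropped under the same
  threshold;
* degree-2 nodes left behind are dissolved, concatenating paths and
  length-weighting diameters.

Each connected component is rooted at its node nearest the disc
center and its edges oriented outward; components whose nearest node
lies beyond 3 disc diameters are discarded as debris. Degree-4 nodes
are vessel crossings, not junctions: their four incident edges are
paired to maximize tangent continuity (each edge with the one closest
to a straight 180° continuation, ties broken by caliber similarity),
the node is removed and the paired edges merged, leaving a forest.
Nodes of degree ≥5 are flagged pathological and excluded from
measurement.

## Caliber estimation

At each retained centerline point the local caliber is measured as the
length of the foreground chord through the point, with the vessel
boundary located at the 0.5-level crossings of the bilinearly
interpolated mask (sub-pixel). Three chords are taken — perpendicular
to the local tangent and at ±20° around it, each projected back onto
the perpendicular — because a single perpendicular chord on a straight
stroke samples one fixed raster phase and can carry a coherent
quantization bias of several tenths of a pixel; the oblique chords
decorrelate the phase. The Euclidean distance transform of the mask
supplies the local radius scale: path points within two local radii of
either end node are excluded, since the parent and daughter strokes of
a junction overlap into a single bulge that remains wider than the
vessel until the strokes separate (geometrically ~(r₁+r₂)/(2·sin(α/2))
along each daughter, i.e. beyond one radius at typical branch angles
α). Edges too short to retain any point fall back to the
distance-transform mean over the whole path and are flagged. On
rendered strokes of known width this estimator is accurate to ±0.3 px
(SD 0.06 px) across widths 3–12 px and arbitrary orientations.

## Ordering and junction classes

Strahler orders live on edges (vessel segments): terminal segments are
order 1 and a parent is `m+1` if at least two daughters attain the
maximal daughter order `m`, else `m`. Orders are therefore
non-increasing from root to leaf and bounded by `⌊log₂(leaves)⌋ + 1`.
A junction with two daughters is a *bifurcation* when the daughter
orders are equal and a *branching point* when they differ; junctions
with more than two daughters are classified on the two
largest-caliber daughters and flagged. The implementation is
cross-checked against an independent post-order recursion on 200
random trees.

## The five metrics

* **Branch angle (BA / BEA).** The angle between the two daughters'
  initial directions. Each direction is the principal axis of the
  daughter path over a window of 3 parent diameters, after skipping
  one parent diameter nearest the junction: the skeleton bends through
  the junction bulge, and the merge point is displaced along the
  bisector by roughly one parent radius, so the first path pixels do
  not represent the daughter's course. Both factors are configurable.
  Junctions whose daughter paths are too short to fit a direction are
  skipped and flagged.
* **Branch coefficient (BC / BEC).** `(d₁² + d₂²)/d₀²` with the
  daughter and parent calibers above — the junction-exponent-2 area
  ratio conventional in retinal branching analysis. BC and BEC share
  one implementation and differ only in which junction class they
  average over.
* **Annulus.** Branch metrics aggregate (unweighted mean) only
  junctions whose node lies 0.5–2.0 disc diameters from the disc
  *edge* (boundaries inclusive, i.e. 1.0–2.5 diameters from the
  center). The restriction is applied to all four branch metrics for
  symmetry of the definitions; a config flag lifts it. Metrics with no
  qualifying junction are NaN, never 0.
* **Main angle (MA).** Among trees rooted within one disc diameter of
  the disc center, the largest-caliber tree above the disc-center row
  and the largest below are taken as the superior and inferior
  arcades. On each, the maximal-Strahler-order chain is followed from
  the root; the distal endpoint of its last maximal-order edge is the
  arcade anchor. MA is the angle at the disc center between the two
  center→anchor rays. The vertex is the disc center by default (a
  configurable override exists); MA is not annulus-restricted. If a
  hemifield has no disc-rooted tree, MA is undefined and flagged.

## Synthetic vasculature

The generator grows a rooted binary tree from a point on the disc
edge, radially outward. Per junction it draws a planned inter-daughter
angle (default uniform 50–95°), a daughter/parent diameter-ratio pair
(default uniform 0.70–0.88 per daughter, sorted so d₁ ≥ d₂), and an
asymmetric split that keeps the larger daughter closer to the parent
course. Segment lengths start at 70 px and decay by 0.82 per level;
the root caliber is 12 px against a 110 px disc (caliber-to-disc ratio
≈ 1/9, matching major arcades at typical fundus resolution). With
probability 0.5 the smaller daughter receives a shallower subtree, so
both junction classes occur; a full symmetric tree would contain only
bifurcations. Arcade pairs place one tree superiorly and one
inferiorly on the temporal side.

Two properties are enforced by deterministic rejection (regrow on the
same RNG stream), because they are preconditions for unambiguous
ground truth rather than claims about real retinas:

* *crossing-free*: non-adjacent strokes keep a clearance of 3 px, so a
  single-class mask contains no vessel overlaps (crossings are tested
  separately with deliberately overlapped strokes);
* *off-lattice*: planned directions stay ≥2° away from the raster axes
  (0°, 45°, 90°, 135°), via a rigid rotation of the daughter pair that
  preserves the planned angle. A lattice-aligned straight stroke keeps
  one sub-pixel phase along its entire length; its rasterized width is
  then off by up to a pixel and no measurement could recover the
  planned caliber. Real vessels curve and never hold such alignment.

Rendering stamps each segment as an exact stadium (capsule) of its
planned diameter — a pixel is foreground iff its center lies within
the half-width of the centerline. Ground truth (junction angles from
planned directions, coefficients from planned diameters, classes from
Strahler orders of the planned tree, the arcade anchor and MA) is
computed analytically from the spec, entirely independent of the
raster pipeline.

The generator emulates what the measurement code needs — known
topology, angles and calibers — and deliberately not what it does not:
vessels are straight per segment and untapered, there is no background
texture, no artery/vein color contrast, no segmentation noise, and no
inter-class crossings within one mask. Passing recovery tests
therefore demonstrates correctness of skeletonization, graph logic,
ordering and measurement at realistic scales; it does not certify
robustness to segmentation errors in clinical masks.

Cohort simulation draws each metric of each image independently from
Normal(mean, SD) per group. Defaults come from the published reference
summaries (group means with 95% CIs of the mean for all five metrics,
both vessel classes, group sizes 279/1193/510/384). The published
tables give CIs rather than SDs, so SDs are recovered as
`(CI half-width / 1.96) · √n` — a documented normal-approximation
inversion, not a published value. With SD = 0 the simulator reproduces
the group means exactly, which is how the printed pairwise mean
differences are regenerated arithmetically.

## Statistics

Descriptives are mean, sample SD (n−1), and a t-based CI of the mean.
The group comparison is a fixed-effects one-way ANOVA (verified
against an independent implementation and by the Σ-of-squares identity
to 10⁻⁸ relative); pairwise mean differences use Fisher's LSD — the
pooled within-group mean square and residual df of the full ANOVA —
matching the common workflow of reporting unadjusted pairwise
p-values next to an omnibus ANOVA. Bonferroni adjustment and Welch
(unpooled, Satterthwaite df) comparisons are selectable in
configuration; the CI level is 95% throughout. Null calibration is
tested: four identical Normal(0,1) groups of 50 reject at α = 0.05 in
5% ± 1.5% of 2 000 replicates.

Images are treated as independent observations (both eyes enter
separately), mirroring the reference cohort's unit of analysis; the
within-subject correlation between fellow eyes is a known, uncorrected
caveat of that design.

Under the reference simulation of the venous main angle (published
means, CI-derived SDs, published group sizes), the noncentral-F power
to reach p < 0.001 is 86.6% per replicate — so while a typical seeded
run yields p ≈ 10⁻⁵–10⁻⁶, roughly one replicate in eight lands above
10⁻³ by construction. The validation suite states the stricter
95-of-100 replicate requirement verbatim and documents this gap rather
than relaxing either side.

## Numerical choices and degenerate inputs

* Problem sizes used in the validation suite — 700² px canvases,
  depth-4 arcade pairs, 50-image recovery corpora, 100 cohort
  replicates, 2 000 calibration replicates — were chosen so each
  property is exercised at realistic vessel scales while the whole
  suite runs in well under a minute per criterion.
* Angle returns are in (0°, 180°]: an exactly-zero angle between unit
  vectors is mapped to 180° only for the degenerate identical-ray case.
* Empty masks produce an empty skeleton with a warning; a per-class
  record is then emitted flagged `no_vasculature` rather than failing
  the image.
* Components with no node within 3 disc diameters raise
  `no rooted vasculature` if nothing else survives.
* Degenerate groups (SD = 0) give a zero-width CI; a zero pooled MSE
  yields p = 0 for unequal means and p = 1 otherwise.
* Ties in crossing pairing are broken by caliber similarity; ties in
  maximal-order chain following by caliber.

## Known limitations

* Segmentation is out of scope: masks arrive pre-classified per vessel
  class, and segmentation noise (gaps, fused vessels, false branches)
  is only partially represented by thinning artifacts.
* The crossing resolver handles degree-4 nodes; degree-≥5 tangles are
  excluded rather than resolved.
* MA depends on a superior/inferior split relative to the disc-center
  row, which presumes roughly upright fundus orientation.
* The caliber estimator assumes locally straight vessels over a few
  pixels; extreme tortuosity at the scale of the vessel width would
  bias chords.
* Cohort simulation treats metrics as independent normals; real
  per-image metrics are correlated and the venous BC group shows a
  heavily skewed published interval that a normal draw only
  caricatures.
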