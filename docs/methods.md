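# Methods

## The curvature model

The per-vertex statistic is a discrete curvature approximation designed for
thresholded CT bone surfaces: at vertex `V_i` with unit normal `N`, every
neighbor `X_j` within `ring` edge-graph steps contributes
`|sin θ_j| = |(X_j − V_i) · N| / ‖X_j − V_i‖`, and `C(V_i)` is the plain
mean of these contributions. The model assumes neighbors are roughly evenly
distributed around the vertex; no area weighting is applied, and none is
offered (a deliberate non-goal — the plain mean is the definition).

Consequences worth knowing:

- `C ∈ [0, 1]` always (Cauchy–Schwarz), 0 on planes, `sin β` at a pyramid
  apex with depression angle β, `sin(φ/2)` on a sphere sampled at angular
  spacing φ. It measures *bending relative to neighbor spacing*, not
  metric curvature: refining a sphere's mesh drives `C → 0`.
- On extruded features (a straight step or ridge) the neighbors running
  along the feature lie in the tangent plane and dilute the mean; `C`
  saturates near 0.5–0.6 rather than 1. Point-like features (spikes,
  jagged fragment edges) reach higher values. This is why the fracture
  phantom models comminution explicitly (below).
- `C` is exactly invariant under uniform scaling and rigid motion, and the
  vectorized implementation is bit-identical to a per-vertex scalar loop
  (both evaluate `X·N − V·N` and `√Σ(X−V)²` through the same reduction
  primitives; the suite asserts exact equality on 50 random meshes).

### Parameters

| parameter | default | meaning |
|---|---|---|
| `ring` | 3 | neighborhood radius in edge steps. Small rings under-react to fractures on fine meshes; large rings blur localized damage. 3 balances the two for the ~0.5 mm-edge meshes the phantoms emulate; it is recorded in every output because results depend on it. |
| normal rule | `area` | vertex normal = normalized area-weighted mean of incident face normals. `uniform` and `angle` are selectable; the rule is recorded in outputs. |
| weld tolerance | 1e-6 mesh units | duplicate-vertex merge distance at OBJ load (CT exports commonly duplicate vertices along strip boundaries). |

The vertex-normal construction is a documented choice, not a transcription:
averaging neighbor *positions* does not yield a vector perpendicular to any
tangent plane, so the standard area-weighted face-normal average is used;
on symmetric configurations (pyramid apex, sphere pole) it reduces to the
symmetry axis, which is what the curvature definition needs.

Winding consistency is not assumed on input: a reorientation pass
propagates consistent winding across shared edges and orients each
component outward by majority vote against the centroid. `|sin θ|` itself
is sign-insensitive, but consistent normals keep the mirroring heuristics
and any exported normals sane.

## Regions of interest and mirroring

ROIs are Euclidean balls (center + radius in mesh coordinates), replacing
interactive picking; geodesic selection was considered and rejected as
under-specified for open, multi-component CT surfaces. ROI area is the
summed area of faces whose three vertices are all selected, which ignores
dangling vertices.

The contralateral region is obtained by reflecting the ROI center across a
mid-sagittal plane — user-supplied, or estimated as the plane through the
vertex centroid whose normal (chosen among the three principal axes of the
vertex covariance) minimizes the mean nearest-neighbor distance between
the mesh and its reflection. The two regions' areas are then equalized:
if they differ by more than 2% (relative to the larger), the larger
region's radius is shrunk by bisection to 1e-3 radius resolution.
Equalization only ever shrinks. Because the *source* region can be the
larger one, the mirroring function returns the adjusted (source, mirrored)
pair rather than the mirrored region alone.

## Histograms and the weighted average

Curvature values are decomposed into ten fixed bins over [0, 1]; bin `k`
is `[0.1k, 0.1(k+1))` with the last bin closed, so every legal value has
exactly one bin. The weighted average of curvature is Σ midpoint ×
proportion of ROI *vertices* (not face area) in each bin. The plain mean
of the raw values is emitted alongside (`raw_mean`) but the weighted
average is the headline statistic: it is what the binned bar charts
display, and linearity in the proportions makes pre/post deltas easy to
attribute to bin shifts.

## Similarity analysis

Bray–Curtis similarity `BC = 2·Σ min / (S_i + S_j)` is computed on bin
*proportions* by default: areas are equalized but vertex counts still
differ slightly between sides, and the proportion basis removes that
nuisance (then `BC = Σ min(p, q) = 1 − ½‖p − q‖₁`, an identity the tests
cross-check). The raw-count basis of the classical definition remains
available.

The z-normalized Euclidean distance z-scores each of the ten bin variables
across a histogram *set* (sample n−1 standard deviation; a zero-variance
bin contributes 0) and takes the Euclidean norm of the difference of two
z-vectors. The z-population is the set passed in; the bilateral workflow
uses one case's four histograms (pre/post × affected/unaffected), and the
population is configurable because the choice materially changes the
scale. Values of the unaffected side are never rescaled between scans —
each scan's original data stand as measured.

Hierarchical clustering is agglomerative on those z-distances with
average (default), complete or single linkage via the Lance–Williams
update. Ties break deterministically on the lexicographically smallest
pair of cluster representatives, making the tree invariant to input
order; scipy's linkage is used as an independent oracle in the tests, not
as the implementation, because the tie-break and the merge-sequence
output type are part of the contract.

## Cohort statistics

Pre/post comparisons use the classic paired t-test (df = n−1, 95% CI,
two-sided p). Identical pre and post vectors return t = 0, p = 1 (the
degenerate no-effect case); zero-variance differences with nonzero mean
raise, since t is undefined there.

Intra-observer reliability uses Fleiss' kappa over repeated measurements.
The measured quantity (weighted average of curvature) is continuous, so
each repeat is first discretized into the ten standard curvature bins;
the one-way random-effects ICC(1,1) is reported alongside as a clearly
labeled continuous-data alternative. The kappa interpretation scale is
the six-band convention: < 0 poor, ≤ 0.20 slight, ≤ 0.40 fair, ≤ 0.60
moderate, ≤ 0.80 substantial, ≤ 1.00 almost perfect; values in [0, 0.01)
map to "slight" (the nearest printed band above "poor").

## Synthetic phantoms

Patient CT surfaces are not redistributable, so the test bed is a family
of generated meshes:

- **plane / pyramid / icosphere** give closed-form curvature values
  (0, sin β, ≈ sin(φ/2)) used as exact oracles.
- **fracture pair**: a 41×41 jittered grid over 20×20 mesh units
  (≈0.5 mm spacing at CT scale) with a gentle sinusoidal base. The
  "pre-op" surface adds a sharp 2 mm step (the clinical displacement
  threshold) and a jagged per-vertex comminution texture (amplitude equal
  to the step height, triangular window of half-width 3 around the
  fracture line) — the two-directional roughness real fracture edges
  have, and the reason pre-op ROI histograms peak in the high bins.
  The "post-op" surface replaces the step with a logistic ramp and keeps
  30% of the texture (reduction is never perfect). Vertex correspondence
  is exact; a zero step yields identical meshes.
- **bilateral**: a 61×41 dome sheet spanning x ∈ [−15, 15], exactly
  mirror-symmetric about x = 0 — jitter, corrugated bone texture *and
  the triangulation's diagonals* are generated on one half and mirrored —
  except for a one-sided conical defect (amplitude 0.8 pre, 0.3 post,
  radius 2) with fragment noise. Zero amplitude gives bit-exact symmetry,
  which pins the BCSI = 1 and distance = 0 baselines.

All generators are bit-reproducible from (parameters, seed); jitter never
exceeds 1% of the grid spacing. What the phantoms do **not** emulate:
anatomical shape, multi-fragment topology changes, CT partial-volume
artifacts, fixation hardware, or slice-reconstruction staircase noise.
Passing phantom tests therefore demonstrates that the *pipeline measures
what it claims* under known geometry — not that any clinical effect size
will transfer to real data.

## Problem sizes and numerical choices

The phantom study uses 20 seeds (20 synthetic "patients"), grids of
1 681–2 501 vertices, and ring 3 — sizes chosen so a full cohort run
completes in seconds while keeping ≥ 90 vertices per ROI so histograms are
stable. The Monte-Carlo type-I-error check of the paired t-test uses 2 000
replicates of 10–12 pairs. Curvature sin values are clamped to 1.0 to
absorb last-ulp Cauchy–Schwarz violations; pair distances below 1e-12 are
treated as welded duplicates and dropped from `m` with a logged count.
Half-open binning puts knife-edge values deterministically: note that
`sin(30°)` in double precision is fractionally below 0.5 and therefore
bins to bin 4, which is why examples avoid asserting values that sit
exactly on a bin edge.

## Known limitations

- The curvature statistic confounds surface bending with mesh resolution;
  comparisons are only meaningful between meshes of similar edge length
  (pre/post CT exports of the same patient satisfy this).
- Euclidean-ball ROIs can capture both cortical plates of a thin bone;
  on real data, choose radii below the local bone thickness or crop first.
- The symmetry-plane estimator assumes approximate bilateral symmetry and
  considers only the three principal axes; strongly asymmetric trauma may
  need a user-supplied plane.
- Fleiss' kappa on discretized continuous measurements depends on the bin
  width at the measurement scale; the ICC is the more informative number
  when repeats cluster within a single bin.
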