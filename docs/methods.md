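# Methods

`facesim` registers a set of open triangular shells — 3D facial scans in
millimetres — into a common frame and measures the pairwise (dis)similarity
of all faces in nearly linear time in the number of faces. This note
documents the model, the numerical choices and the synthetic fixtures, and
what the shipped tests do and do not demonstrate.

## Surface distance model

For a point `v` and a face `f` (an indexed triangle mesh), `near(v, f)` is
the closest point anywhere on the polygonal surface of `f` — triangle
interiors, edges and vertices, not just mesh vertices. Two reductions make
the per-vertex mapping deterministic and meaningful:

* **Uniqueness.** A vertex whose nearest neighbor is not unique (two closest
  points at numerically the same distance on spatially distinct parts of the
  surface) is excluded from all means. On real scans such ties are rare
  (order 0.01% of vertices); they are noise, not signal.
* **Auto-cropping.** A vertex whose nearest neighbor lies on a *boundary
  edge* (an edge incident to exactly one triangle) or boundary vertex of the
  other mesh sits over area the other surface does not cover — ragged scan
  margins and hole rims. Under cropping these vertices are excluded too.

The directional cost `d_avg(f_i, f_j)` is the arithmetic mean of
`‖v − near(v, f_j)‖` over the retained vertices of `f_i`; the mutual
distance is the symmetric

```
dist(f_i, f_j) = max(d_avg(f_i, f_j), d_avg(f_j, f_i))
```

a modified Hausdorff distance that averages rather than taking the supremum,
which makes it robust to noise and outliers.

## Nearest-surface queries

Exact closest-point queries are accelerated with a k-d tree over triangle
centroids (`scipy.spatial.cKDTree`). For a query point, K candidate
triangles are retrieved and projected exactly (vectorized point-to-triangle
projection with the standard Voronoi-region case analysis); K grows until a
provable lower bound — the distance to the K-th centroid minus the largest
centroid-to-corner radius in the mesh — exceeds the best exact distance
found. Results are therefore identical to a brute-force scan over all
triangles, which the test suite checks against an independently formulated
oracle (plane projection plus clamped edge segments).

Numerical realizations of the reductions:

* tie: a second candidate whose distance is within `1e-9` (relative) of the
  minimum and whose closest point lies more than `1e-6` mm away from the
  winner (so candidates sharing the winning point across a common edge are
  not ties);
* boundary hit: a barycentric coordinate below `1e-9` on a boundary edge, or
  a winner at a boundary vertex.

Both tolerances are module constants and can be overridden per query.

## ICP registration

One-directional ICP aligns a moving mesh onto a fixed surface: pair sampled
moving vertices with their closest points, estimate the least-squares rigid
transform in closed form (orthogonal Procrustes / Kabsch, reflection
excluded; uniform scale by Umeyama's estimator behind `allow_scale`),
compose, repeat. The objective is the plain point-to-point mean distance —
no point-to-plane term. Design choices:

* **First iteration uncropped.** Cropping is disabled in iteration 1 and
  enabled from iteration 2 (`crop_after_first`), so poorly overlapping
  initial poses still converge toward each other.
* **Sampling drawn once.** The vertex sub-sample (default 1000 random
  vertices) is drawn once per registration, not per iteration, which keeps
  the stopping statistic stable. `random`, `uniform_grid` (bisected cell
  size targeting ±10% of the requested count), `curvature` (largest absolute
  angle-deficit Gaussian curvature, ties broken by vertex index) and `none`
  are available; random sampling at 1000 vertices is the recommended
  default.
* **Stopping rule.** The registration stops when the sampled `d_avg` changes
  by less than 5% *relative* between consecutive iterations
  (`delta_threshold = 0.05`), or at `max_iterations = 100`, or when `d_avg`
  falls below an absolute numerical floor of `1e-9` mm. The relative reading
  matters: on genuinely different faces `d_avg` plateaus at the real shape
  difference and the rule fires after a handful of iterations, while on a
  noise-free copy the improvement ratio stays high and the registration runs
  on to exact recovery instead of stalling at an arbitrary absolute level.
* **No pre-alignment by default.** A rough initial alignment is assumed, as
  is standard for ICP; an optional centroid-translation initializer is
  available behind `center_initialize`.

Point-to-point ICP on open shells has a characteristic weak mode: tangential
sliding along the surface is only constrained where the surface has slope,
so registration accuracy and speed depend on the relief of the scanned
geometry. This is a property of the method class, not of this
implementation; it drives the design of the synthetic generator below.

## Batch registration (GPA loop)

A template face chosen by the analyst is cloned as the initial average face.
Each round: (1) every face — including the template's source — is registered
onto the current average by ICP, warm-started from its previous pose;
(2) every average-face vertex is displaced by the mean offset to its closest
points on the registered faces, skipping faces where the neighbor is
non-unique or (under cropping) on a border; vertices with no usable neighbor
stay put, and more than 50% such vertices aborts with a degenerate-population
error; (3) the loop stops when the mutual distance between consecutive
average faces drops below `psm_threshold = 0.3` mm, a Procrustes-style
surface convergence metric, or after `max_gpa_iterations = 10`. Faces that
lose all overlap are excluded permanently with a warning; the run continues
while at least two remain. Each iteration costs one ICP registration and one
averaging pass per face — linear in the number of faces — and a handful of
iterations suffice in practice.

Average-face vertex normals are recomputed after every averaging step; the
signed (relative) indirect measure depends on them.

## Indirect (gauge) measurement

After batch registration the average face acts as a measurement gauge. One
nearest-surface query per (average vertex, face) fills a cache: the closest
3D point for the *euclidean* method, or a signed scalar for the *relative*
method (positive when the face lies in the half-space of the average-face
vertex normal; a zero dot product counts as positive). Pairwise entries are
then assembled from the cache alone — no further surface queries — averaging
per-vertex values over the average-face vertices valid for *both* faces of a
pair:

* euclidean: `‖near(v, f_i) − near(v, f_j)‖`
* relative: `|d_r(v, f_i) − d_r(v, f_j)|`

Vertices invalid for exactly one face are excluded from that pair only, not
globally. A pair with no jointly valid vertex yields a missing entry,
serialized as an empty CSV cell, never 0. Cells are independent, so any
execution order (or parallel schedule) gives identical results; the
single-threaded implementation is the reference.

Two quadratic-cost baselines exist for validation at small N: `BL` registers
every pair bidirectionally at full resolution and keeps the direction with
the smaller cropped distance; `FR` assumes batch-registered inputs and
measures each pair directly. `crop_to_average` restricts direct measurement
to vertices whose neighbor on the average face is usable, so direct and
gauge-based values cover the same surface area and are comparable.

## Synthetic fixtures

No real scan database ships with the package; the generator produces
fixtures that emulate the geometric properties of stereophotogrammetric
facial scans:

* an **ellipsoid-cap base** (semi-axes 1.0/0.8/1.15 of a 100 mm nominal
  radius over a 120 mm square footprint). The cap is deliberately
  non-spherical: a spherical cap is rotationally symmetric about its axis,
  which makes rigid pose unidentifiable for any surface-distance-based
  registration — a pathology real faces do not have;
* **multi-scale Gaussian relief** (default 150 bumps, amplitudes up to 6 mm,
  widths 4–8 mm) along the radial direction. Local slopes reach order 1, as
  they do on real noses, orbits and lips; this is what makes point-to-point
  ICP well-conditioned on faces;
* **holes** (triangles cut around random interior centers), **ragged
  borders** (jittered boundary vertices), per-face **border trims** (random
  margins cut from the four grid sides, emulating independently trimmed
  scans) and i.i.d. Gaussian **vertex noise** (default σ = 0.05 mm, typical
  scanner noise);
* populations share the base shape, add smooth per-face shape variation
  (default 2 mm amplitude, giving pairwise distances in the sub-mm to few-mm
  range observed between real faces) and a recorded random rigid
  displacement (default ≤10° / ≤10 mm) for ground-truth recovery tests.

The default 48×48 grid (~2.3k vertices) keeps the full pipeline interactive;
real scans are an order of magnitude denser but geometrically similar, and
all algorithms are resolution-agnostic. What the fixtures do *not* emulate:
anatomically realistic face shape statistics (no morphable model),
expression or pose variation, scanning artifacts beyond holes/ragged borders
(e.g., smeared geometry from hair), and non-uniform vertex densities.
Passing tests therefore demonstrate the geometric and algorithmic
correctness of the pipeline and the qualitative phenomena (cropping reduces
asymmetry, indirect tracks direct measurement), not recognition performance
on real populations.

## Degenerate inputs and edge cases

* Zero-area triangles are dropped at load with a warning; STL is de-indexed
  by merging coincident vertices.
* Transform estimation needs ≥3 non-collinear pairs (second singular value
  above `1e-9` relative); otherwise a degenerate-pairing error.
* Isolated vertices get NaN normals and are excluded from signed-distance
  use.
* Fewer than 2 registrable faces, or an empty retained vertex set, raise
  typed errors (`DegeneratePopulationError`, `InsufficientOverlapError`)
  rather than returning silently wrong numbers.

## Known limitations

* One-directional ICP with auto-cropping assumes reasonably dense, roughly
  uniformly sampled meshes; strongly mismatched resolutions reintroduce
  asymmetry.
* No global pre-alignment: initial poses beyond roughly 20–30° may converge
  to a wrong local minimum.
* The GPA convergence metric is the mutual distance between consecutive
  average faces — a surrogate for a full Procrustes surface metric, used
  with the same 0.3 threshold.
* Template choice affects the average face slightly; selection is left to
  the analyst (`template_index`).
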