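# facesim

Batch registration and mutual similarity measurement of 3D facial scans in
nearly linear time.

## The problem

Biological anthropologists quantify facial (dis)similarity — *biodistance* —
from stereophotogrammetric 3D scans: open triangular shells in millimetres
with ragged borders and occasional holes, and no landmark annotations. The
classical workflow registers and measures every pair of scans independently
(ICP alignment plus a surface-to-surface distance), which is accurate but
quadratic in the number of faces: hours to days for a few hundred scans.

`facesim` implements a nearly linear batch (N:N) pipeline:

1. **Batch registration.** A generalized-Procrustes loop around
   one-directional ICP. A chosen template face is cloned and progressively
   transmuted into the population's *average face*: each round, every face
   is ICP-registered onto the current average, and every average vertex
   moves to the centroid of its nearest neighbors across the registered
   faces, until the change between consecutive averages falls below a
   threshold. Each round is linear in the number of faces.
2. **Indirect measurement.** The average face becomes a measurement gauge:
   one nearest-surface query per (average vertex, face) fills a cache — the
   closest points themselves, or signed normal-referenced distances — and
   all pairwise distances are then assembled from the cache without any
   further surface queries.

Robustness comes from two reductions applied throughout. With the reduced
surface `f̄_i` (vertices of `f_i` with exactly one nearest neighbor on
`f_j`), the directional cost and the mutual distance are

```
d_avg(f_i, f_j) = (1/|f̄_i|) Σ_{v ∈ f̄_i} ‖v − near(v, f_j)‖
dist(f_i, f_j)  = max(d_avg(f_i, f_j), d_avg(f_j, f_i))
```

a modified Hausdorff distance (mean instead of supremum). *Auto-cropping*
additionally excludes vertices whose nearest neighbor lies on a boundary
edge of the other mesh — they sit over non-overlapping area (ragged margins,
hole rims) — which both cleans the measurement and suppresses the asymmetry
of one-directional ICP. Nearest neighbors are exact closest points anywhere
on the polygonal surface, found with a k-d tree over triangle centroids plus
exact point-to-triangle projection.

See `docs/methods.md` for the full model, parameter and tolerance choices,
and limitations.

## Worked example

Since no scan database ships with the package, the synthetic generator
provides facial-shell fixtures (open bumpy ellipsoid-cap domes with holes,
ragged borders and noise, at facial scale in mm):

```python
import numpy as np
from facesim import (GPAConfig, ICPConfig, apply_transform, build_cache,
                     generate_population, gpa_register, indirect_matrix,
                     PopulationSpec, vertex_normals)

spec = PopulationSpec(n_faces=5, seed=7)          # 2 mm shape variation,
faces, _ = generate_population(spec)              # <=10 deg / 10 mm jitter
result = gpa_register(faces, GPAConfig(template_index=0,
                                       icp=ICPConfig(seed=1)))
print("GPA iterations:", result.iterations_run,
      "final metric: %.3f mm" % result.metric_history[-1])

registered = [apply_transform(f, t) for f, t in zip(faces, result.transforms)]
average = result.average_face
average.normals = vertex_normals(average)
cache = build_cache(average, registered, method="relative")
matrix = indirect_matrix(cache)
print(matrix.to_dataframe().round(2))
```

which prints

```
GPA iterations: 2 final metric: 0.056 mm
        face_0  face_1  face_2  face_3  face_4
face_0    0.00    0.91    0.97    0.99    0.82
face_1    0.91    0.00    0.81    0.60    0.70
face_2    0.97    0.81    0.00    0.72    0.76
face_3    0.99    0.60    0.72    0.00    0.68
face_4    0.82    0.70    0.76    0.68    0.00
```

The batch registration converged in 2 rounds (the change between consecutive
average faces fell to 0.056 mm, below the 0.3 mm threshold). Each matrix
cell is the indirect mutual distance of two faces in millimetres, measured
through the average-face gauge — 0 on the diagonal, symmetric, and here in
the sub-millimetre range matching the 2 mm generator shape variation;
larger values mean less similar faces.

## Command line

The same pipeline is available from a shell, for directories of OBJ/PLY/STL
files:

```sh
facesim synth --n-faces 10 --out scans/          # synthetic test population
facesim nn-analyze scans/ --template 0 --method relative --out results/
```

`nn-analyze` writes the average face (`average_face.ply`), per-face 4x4
transforms (`transforms.json`), the symmetric distance matrix
(`distance_matrix.csv`, missing pairs as empty cells), a long-format pair
table, a convergence log and run metadata for exact reproduction.
`register` and `measure` run the two stages separately; `--mode bl` / `--mode
fr` select the slow exact baselines for validation at small N, and
`--heatmap` renders a PNG (darker = more similar).

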