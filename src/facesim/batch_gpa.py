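"""Batch (N:N) registration: a generalized-Procrustes loop around
one-directional ICP, transmuting a cloned template face into the population's
average face.

The loop: (1) clone a chosen template face as the initial average face;
(2) register every face onto the current average by ICP; (3) displace every
average-face vertex by the mean offset to its closest points on the
registered faces ("toward the centroids of nearest neighbors"); (4) repeat
until the mutual distance between consecutive average faces falls below a
threshold.  Each iteration is linear in the number of faces, and a handful of
iterations suffice in practice, so the whole batch registration runs in
nearly linear time.

The template itself participates as an ordinary population member and is
registered like any other face.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .mesh_core import RigidTransform, TriMesh, apply_transform, vertex_normals
from .proximity import InsufficientOverlapError, build_index
from .registration import ICPConfig, icp_register
from .similarity import dist

logger = logging.getLogger(__name__)

__all__ = [
    "GPAConfig",
    "GPAResult",
    "DegeneratePopulationError",
    "average_position",
    "update_average_face",
    "convergence_metric",
    "gpa_register",
]


class DegeneratePopulationError(ValueError):
    """Too few usable faces / vertices to form an average face."""


@dataclass
class GPAConfig:
    """Batch-registration settings.

    ``psm_threshold`` terminates the loop when the surface metric between
    consecutive average faces (a Procrustes-style convergence measure) drops
    below it.
    """

    template_index: int = 0
    psm_threshold: float = 0.3
    max_gpa_iterations: int = 10
    crop: bool = True
    icp: ICPConfig = field(default_factory=ICPConfig)

    def __post_init__(self) -> None:
        if not self.psm_threshold > 0:
            raise ValueError("psm_threshold must be positive")
        if self.max_gpa_iterations < 1:
            raise ValueError("max_gpa_iterations must be >= 1")


@dataclass
class GPAResult:
    """Outcome of a batch registration."""

    average_face: TriMesh
    transforms: list[RigidTransform]
    metric_history: list[float]
    converged: bool
    excluded_faces: list[int]
    icp_iterations: list[int]

    @property
    def iterations_run(self) -> int:
        return len(self.metric_history)


def average_position(
    v: np.ndarray, neighbor_points: np.ndarray, usable: np.ndarray
) -> np.ndarray:
    """New position of a template vertex: displaced by the mean offset to its
    usable nearest neighbors across the population.

    ``usable`` masks out faces where the neighbor was non-unique or cropped.
    With no usable face the vertex is left unchanged (callers flag it).
    """
    if not np.any(usable):
        return np.asarray(v, dtype=float)
    offsets = neighbor_points[usable] - v
    return np.asarray(v, dtype=float) + offsets.mean(axis=0)


def update_average_face(
    template: TriMesh,
    faces: list[TriMesh],
    crop: bool = True,
) -> TriMesh:
    """Move every template vertex toward the centroid of its nearest neighbors
    on the registered faces; topology is preserved and normals recomputed.

    A vertex skips faces on which its nearest neighbor is non-unique or —
    under cropping — lies on the face's border.  Raises when more than half
    of the vertices have no usable neighbor at all.
    """
    pts = template.vertices
    n = len(pts)
    sums = np.zeros((n, 3))
    counts = np.zeros(n)
    for f in faces:
        hits = build_index(f).query(pts)
        ok = hits.unique.copy()
        if crop:
            ok &= ~hits.on_boundary
        sums[ok] += hits.closest_points[ok] - pts[ok]
        counts[ok] += 1
    usable = counts > 0
    if usable.sum() < 0.5 * n:
        raise DegeneratePopulationError(
            f"only {int(usable.sum())}/{n} average-face vertices have usable "
            "neighbors"
        )
    new_pts = pts.copy()
    new_pts[usable] += sums[usable] / counts[usable, None]
    out = TriMesh(new_pts, template.triangles.copy())
    out.normals = vertex_normals(out)
    return out


def convergence_metric(prev_avg: TriMesh, new_avg: TriMesh) -> float:
    """Surface metric between consecutive average faces: their mutual
    (modified Hausdorff) distance, used as the Procrustes-style termination
    measure of the batch loop."""
    return dist(prev_avg, new_avg, crop=True)


def gpa_register(faces: list[TriMesh], config: GPAConfig | None = None) -> GPAResult:
    """Register a population of faces into a common frame via the GPA loop.

    Returns the final average face, one cumulative transform per input face
    (mapping its original pose into the common frame), and the per-iteration
    convergence metric.  Faces that lose all overlap during registration are
    excluded from averaging (permanently) with a warning; the run continues
    while at least two faces remain.
    """
    config = config or GPAConfig()
    n = len(faces)
    if n < 2:
        raise ValueError("batch registration needs at least 2 faces")
    if not 0 <= config.template_index < n:
        raise ValueError("template_index out of range")

    average = faces[config.template_index].copy()
    average.normals = vertex_normals(average)
    transforms = [RigidTransform.identity() for _ in range(n)]
    excluded: list[int] = []
    metric_history: list[float] = []
    icp_iterations = [0] * n
    converged = False
    rng = np.random.default_rng(config.icp.seed)

    for it in range(1, config.max_gpa_iterations + 1):
        avg_index = build_index(average)
        registered: list[TriMesh] = []
        reg_ok: list[int] = []
        for i, face in enumerate(faces):
            if i in excluded:
                continue
            icp_cfg = ICPConfig(**{**config.icp.to_dict(),
                                   "seed": int(rng.integers(2**31))})
            try:
                res = icp_register(face, avg_index, icp_cfg,
                                   initial=transforms[i])
            except InsufficientOverlapError as exc:
                logger.warning("face %d excluded from batch registration: %s",
                               i, exc)
                excluded.append(i)
                continue
            transforms[i] = res.transform
            icp_iterations[i] += res.iterations_run
            registered.append(apply_transform(face, res.transform))
            reg_ok.append(i)
        if len(registered) < 2:
            raise DegeneratePopulationError(
                "fewer than 2 faces remain registrable"
            )
        new_average = update_average_face(average, registered, crop=config.crop)
        metric = convergence_metric(average, new_average)
        metric_history.append(metric)
        logger.info("GPA iteration %d: convergence metric %.4f mm", it, metric)
        average = new_average
        if metric < config.psm_threshold:
            converged = True
            break

    return GPAResult(
        average_face=average,
        transforms=transforms,
        metric_history=metric_history,
        converged=converged,
        excluded_faces=sorted(excluded),
        icp_iterations=icp_iterations,
    )
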