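"""Surface distance measures: direct (mean nearest-neighbor / modified
Hausdorff) and indirect (average-face gauge) variants.

The directional cost ``d_avg(fi, fj)`` is the arithmetic mean distance from
the retained vertices of ``fi`` to their closest points anywhere on the
surface of ``fj``.  Retention drops vertices with a non-unique nearest
neighbor (nondeterministic pairing) and, under auto-cropping, vertices whose
nearest neighbor lies on the border of ``fj`` (non-overlapping area, e.g.
ragged scan margins and hole rims).  The symmetric mutual distance ``dist``
is the larger of the two directional means — a modified Hausdorff distance
that averages instead of taking the supremum, robust to noise and outliers.

The indirect measures approximate a pair's distance through a registered
average face acting as a gauge: for each average-face vertex either the
Euclidean distance between its two cached closest points, or the absolute
difference of two signed normal-referenced distances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh_core import TriMesh, vertex_normals
from .proximity import InsufficientOverlapError, SurfaceIndex, build_index

__all__ = [
    "DirectionalDistance",
    "d_avg",
    "dist",
    "relative_distance",
    "signed_distances",
    "indirect_euclidean",
    "indirect_relative",
    "indirect_distance",
]


@dataclass(frozen=True)
class DirectionalDistance:
    """Mean distance (mm) from one face to another, with exclusion counts."""

    value: float
    n_used: int
    n_excluded_tie: int
    n_excluded_crop: int


def _as_index(f: TriMesh | SurfaceIndex) -> SurfaceIndex:
    return f if isinstance(f, SurfaceIndex) else build_index(f)


def d_avg(
    fi: TriMesh,
    fj: TriMesh | SurfaceIndex,
    crop: bool = True,
    samples: np.ndarray | None = None,
) -> DirectionalDistance:
    """Directional distance cost: mean over retained vertices of ``fi`` of the
    distance to the closest point on ``fj``'s surface.

    ``samples`` restricts the measured vertex set (used with sub-sampling);
    retention rules are applied after sampling.
    """
    target = _as_index(fj)
    idx = np.arange(fi.n_vertices) if samples is None else np.asarray(samples)
    hits = target.query(fi.vertices[idx])
    keep = hits.unique.copy()
    n_tie = int((~keep).sum())
    n_crop = 0
    if crop:
        drop = keep & hits.on_boundary
        n_crop = int(drop.sum())
        keep &= ~hits.on_boundary
    n_used = int(keep.sum())
    if n_used == 0:
        raise InsufficientOverlapError(
            "d_avg: no vertex retained (insufficient overlap)"
        )
    return DirectionalDistance(
        value=float(hits.distances[keep].mean()),
        n_used=n_used,
        n_excluded_tie=n_tie,
        n_excluded_crop=n_crop,
    )


def dist(fi: TriMesh, fj: TriMesh, crop: bool = True) -> float:
    """Mutual (modified Hausdorff) distance: max of the two directional means.

    Symmetric by construction: ``dist(fi, fj) == dist(fj, fi)`` exactly.
    """
    index_i = _as_index(fi)
    index_j = _as_index(fj)
    dij = d_avg(fi, index_j, crop=crop).value
    dji = d_avg(fj, index_i, crop=crop).value
    return max(dij, dji)


def signed_distances(
    points: np.ndarray, normals: np.ndarray, f: SurfaceIndex
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Signed normal-referenced distances of many points to a surface.

    Sign is positive when the closest point lies in the half-space of the
    point's normal (the surface is "in front of" the gauge), negative behind;
    a zero dot product counts as positive.

    Returns ``(signed, unique, on_boundary)`` arrays.
    """
    hits = f.query(points)
    v = hits.closest_points - points
    front = np.einsum("ij,ij->i", v, normals) >= 0
    signed = np.where(front, hits.distances, -hits.distances)
    return signed, hits.unique, hits.on_boundary


def relative_distance(v: np.ndarray, normal: np.ndarray, f: SurfaceIndex) -> float:
    """Signed distance of a single point ``v`` (with unit ``normal``) to ``f``."""
    signed, _, _ = signed_distances(
        np.asarray(v, dtype=float)[None, :], np.asarray(normal, dtype=float)[None, :], f
    )
    return float(signed[0])


def indirect_euclidean(
    v: np.ndarray, fi: SurfaceIndex, fj: SurfaceIndex
) -> float:
    """Euclidean distance between the closest points of ``v`` on the two faces."""
    v = np.asarray(v, dtype=float)[None, :]
    pi = fi.query(v).closest_points[0]
    pj = fj.query(v).closest_points[0]
    return float(np.linalg.norm(pi - pj))


def indirect_relative(
    v: np.ndarray, normal: np.ndarray, fi: SurfaceIndex, fj: SurfaceIndex
) -> float:
    """Absolute difference of the signed distances of ``v`` to the two faces."""
    return abs(
        relative_distance(v, normal, fi) - relative_distance(v, normal, fj)
    )


def indirect_distance(
    fa: TriMesh,
    fi: TriMesh | SurfaceIndex,
    fj: TriMesh | SurfaceIndex,
    method: str = "relative",
    crop: bool = True,
) -> float:
    """Mean indirect distance of ``fi`` and ``fj`` measured via the gauge ``fa``.

    Averages the per-vertex indirect measure over the average-face vertices
    with exactly one nearest neighbor on *each* face (and, under cropping,
    neighbors not on either face's border).  Exactly symmetric in ``fi, fj``.
    """
    if method not in ("euclidean", "relative"):
        raise ValueError(f"unknown indirect method {method!r}")
    ii = _as_index(fi)
    ij = _as_index(fj)
    pts = fa.vertices
    normals = fa.normals if fa.normals is not None else vertex_normals(fa)
    hi = ii.query(pts)
    hj = ij.query(pts)
    valid = hi.unique & hj.unique
    if crop:
        valid &= ~hi.on_boundary & ~hj.on_boundary
    if method == "relative":
        valid &= ~np.any(np.isnan(normals), axis=1)
    if not np.any(valid):
        raise InsufficientOverlapError(
            "indirect_distance: no gauge vertex valid for both faces"
        )
    if method == "euclidean":
        per_vertex = np.linalg.norm(
            hi.closest_points[valid] - hj.closest_points[valid], axis=1
        )
    else:
        vi = hi.closest_points[valid] - pts[valid]
        vj = hj.closest_points[valid] - pts[valid]
        nrm = normals[valid]
        si = np.where(np.einsum("ij,ij->i", vi, nrm) >= 0, 1.0, -1.0)
        sj = np.where(np.einsum("ij,ij->i", vj, nrm) >= 0, 1.0, -1.0)
        per_vertex = np.abs(
            si * hi.distances[valid] - sj * hj.distances[valid]
        )
    return float(per_vertex.mean())
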