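"""Shared fixtures and independent geometric oracles.

The closest-point oracle here deliberately uses a different formulation than
the package (unconstrained projection onto the triangle plane, then clamping
to the three edge segments) so that agreement between the two is a real
cross-check, not a tautology.
"""

from __future__ import annotations

import numpy as np
import pytest

from facesim import ShellParams, TriMesh, flat_grid, generate_shell


# ---------------------------------------------------------------------------
# independent closest-point oracle


def _point_segment_closest(p, a, b):
    ab = b - a
    t = np.clip(np.dot(p - a, ab) / np.dot(ab, ab), 0.0, 1.0)
    return a + t * ab


def oracle_closest_on_triangle(p, tri):
    """Closest point of p on triangle by plane projection + edge clamping."""
    a, b, c = tri
    n = np.cross(b - a, c - a)
    n = n / np.linalg.norm(n)
    proj = p - np.dot(p - a, n) * n
    # barycentric of the projection
    m = np.column_stack([b - a, c - a])
    uv, *_ = np.linalg.lstsq(m, proj - a, rcond=None)
    u, v = uv
    candidates = []
    if u >= 0 and v >= 0 and u + v <= 1:
        candidates.append(proj)
    for e0, e1 in ((a, b), (b, c), (c, a)):
        candidates.append(_point_segment_closest(p, e0, e1))
    dists = [np.linalg.norm(p - q) for q in candidates]
    return candidates[int(np.argmin(dists))]


def oracle_nearest_on_mesh(p, mesh: TriMesh):
    """Exhaustive closest point over every triangle of the mesh."""
    best_d, best_q = np.inf, None
    for tri in mesh.vertices[mesh.triangles]:
        q = oracle_closest_on_triangle(np.asarray(p, float), tri)
        d = np.linalg.norm(p - q)
        if d < best_d:
            best_d, best_q = d, q
    return best_q, best_d


def count_boundary_loops(mesh: TriMesh) -> int:
    """Number of connected boundary loops, by traversal of the boundary-edge
    graph (brute-force tally of edges with triangle incidence one)."""
    from collections import defaultdict

    tally: dict[tuple[int, int], int] = defaultdict(int)
    for t in mesh.triangles:
        for k in range(3):
            e = tuple(sorted((int(t[k]), int(t[(k + 1) % 3]))))
            tally[e] += 1
    adj = defaultdict(set)
    for (a, b), c in tally.items():
        if c == 1:
            adj[a].add(b)
            adj[b].add(a)
    seen: set[int] = set()
    loops = 0
    for start in adj:
        if start in seen:
            continue
        loops += 1
        stack = [start]
        while stack:
            v = stack.pop()
            if v in seen:
                continue
            seen.add(v)
            stack.extend(adj[v] - seen)
    return loops


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture(scope="session")
def small_shell() -> TriMesh:
    """Clean ~1k-vertex bumpy shell (no noise/holes/raggedness)."""
    return generate_shell(
        ShellParams(resolution=32, seed=11, noise_sigma=0.0, raggedness=0.0,
                    hole_count=0)
    )


@pytest.fixture(scope="session")
def artifact_shell() -> TriMesh:
    """Shell with holes, ragged border and noise — every exclusion path."""
    return generate_shell(ShellParams(resolution=40, seed=5))


@pytest.fixture(scope="session")
def plane_pair():
    """Two parallel 10x10 unit grids, 2 mm apart along the normal."""
    return flat_grid(10, 1.0, 0.0), flat_grid(10, 1.0, 2.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
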