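"""Synthetic open-shell generator emulating stereophotogrammetric facial scans.

Real facial scans are open triangle shells in millimetres with ragged,
non-uniform borders, occasional holes from preprocessing (beard, eyes,
nostrils), smooth anatomical relief of a few millimetres and sub-0.1 mm
scanner noise.  The generator emulates those properties on a spherical-cap
dome over a square grid: Gaussian bumps along the surface normal provide
relief, triangles are cut out around hole centers, boundary vertices are
jittered, and i.i.d. Gaussian noise perturbs every vertex.  Populations share
the dome-plus-bumps base shape, add per-face smooth shape variation, per-face
border trims / holes / raggedness, and a recorded random rigid displacement,
so registration can be validated against known ground truth.

Everything is deterministic per seed (NumPy ``default_rng``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mesh_core import RigidTransform, TriMesh, boundary_vertices

__all__ = [
    "ShellParams",
    "PopulationSpec",
    "DegenerateParamsError",
    "generate_shell",
    "generate_population",
    "flat_grid",
    "random_rigid_transform",
]


class DegenerateParamsError(ValueError):
    """Shell parameters removed every triangle."""


@dataclass
class ShellParams:
    """Parameters of one synthetic facial shell.

    The dome spans a square of half-width ``0.6 * dome_radius`` (about
    120 mm across at the 100 mm default — facial-scan scale).  ``resolution``
    is vertices per grid side; the 48 default yields ~2.3k vertices / ~4.4k
    triangles, a working scale at which the full pipeline stays interactive
    while exercising every geometric feature of real scans.
    """

    resolution: int = 48
    dome_radius: float = 100.0
    bump_count: int = 150
    bump_amplitude: float = 6.0
    bump_width: float = 8.0
    hole_count: int = 2
    hole_radius: float = 5.0
    raggedness: float = 2.0
    noise_sigma: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.resolution < 4:
            raise ValueError("resolution must be >= 4")
        for name in ("bump_amplitude", "bump_width", "hole_radius",
                     "raggedness", "noise_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class PopulationSpec:
    """A population of shells sharing a base shape.

    ``variation_amplitude`` controls smooth per-face shape differences
    (low-mm pairwise surface distances, the scale observed between distinct
    human faces); ``jitter_*`` bound the recorded random rigid displacement;
    ``border_trim_max`` trims each face's four grid sides by an independent
    random margin, producing the asymmetric non-overlapping borders typical
    of independently trimmed scans.
    """

    n_faces: int = 10
    base: ShellParams = field(default_factory=ShellParams)
    variation_amplitude: float = 2.0
    variation_count: int = 8
    variation_width: float = 20.0
    jitter_rot_deg: float = 10.0
    jitter_trans: float = 10.0
    border_trim_max: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_faces < 2:
            raise ValueError("a population needs at least 2 faces")


def flat_grid(
    n_side: int = 10, spacing: float = 1.0, z: float = 0.0,
    origin: tuple[float, float] = (0.0, 0.0),
) -> TriMesh:
    """Planar square grid in the z = const plane, counter-clockwise winding
    seen from +z (normals point up).  An analytic fixture for exactness tests.
    """
    xs = origin[0] + spacing * np.arange(n_side)
    ys = origin[1] + spacing * np.arange(n_side)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    vertices = np.column_stack(
        [gx.ravel(), gy.ravel(), np.full(n_side * n_side, float(z))]
    )
    return TriMesh(vertices, _grid_triangles(n_side, n_side))


def _grid_triangles(nx: int, ny: int) -> np.ndarray:
    """Two CCW triangles per grid quad; vertex id = i * ny + j."""
    i, j = np.meshgrid(np.arange(nx - 1), np.arange(ny - 1), indexing="ij")
    v00 = (i * ny + j).ravel()
    v10 = ((i + 1) * ny + j).ravel()
    v11 = ((i + 1) * ny + j + 1).ravel()
    v01 = (i * ny + j + 1).ravel()
    # winding (v00, v10, v11)/(v00, v11, v01) is CCW from above when x grows
    # with i and y with j
    return np.concatenate(
        [np.column_stack([v00, v10, v11]), np.column_stack([v00, v11, v01])]
    )


def _dome(params: ShellParams) -> tuple[np.ndarray, np.ndarray]:
    """Ellipsoid-cap dome over a square grid; returns (vertices, triangles).

    The cap is deliberately elliptical (semi-axes 1.0/0.8/1.15 of the nominal
    radius): faces are narrower than tall and deeper than wide, and — unlike
    a spherical cap — an ellipsoid cap has no rotational symmetry, so rigid
    pose is identifiable from the surface alone.
    """
    res = params.resolution
    a = params.dome_radius
    b = 0.8 * params.dome_radius
    c = 1.15 * params.dome_radius
    w = 0.6 * params.dome_radius
    xs = np.linspace(-w, w, res)
    gx, gy = np.meshgrid(xs, xs, indexing="ij")
    gz = c * np.sqrt(np.maximum(1.0 - gx**2 / a**2 - gy**2 / b**2, 0.0))
    vertices = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    return vertices, _grid_triangles(res, res)


def _radial_bumps(
    vertices: np.ndarray,
    rng: np.random.Generator,
    count: int,
    amplitude: float,
    width: float,
    extent: float,
) -> np.ndarray:
    """Displace vertices along the radial direction by a sum of signed
    Gaussian bumps centered within ``extent`` of the dome apex.

    Bump widths vary between 0.5x and 1.5x the nominal width, giving the
    multi-scale relief (broad cheeks-scale undulation down to steep
    nose-flank-scale features) that makes surface-based rigid alignment
    well-conditioned, as it is on real faces.
    """
    if count == 0 or amplitude == 0:
        return vertices
    radial = vertices / np.linalg.norm(vertices, axis=1, keepdims=True)
    out = vertices.copy()
    for _ in range(count):
        angle = rng.uniform(0, 2 * np.pi)
        rad = extent * np.sqrt(rng.uniform())
        center_xy = rad * np.array([np.cos(angle), np.sin(angle)])
        amp = rng.uniform(0.4, 1.0) * amplitude * rng.choice([-1.0, 1.0])
        bump_w = rng.uniform(0.5, 1.0) * width
        d2 = ((vertices[:, :2] - center_xy) ** 2).sum(axis=1)
        out += (amp * np.exp(-d2 / (2 * bump_w**2)))[:, None] * radial
    return out


def _drop_triangles(vertices, triangles, keep_tri):
    """Remove triangles and any vertices that become unreferenced."""
    triangles = triangles[keep_tri]
    if len(triangles) == 0:
        raise DegenerateParamsError("all triangles removed")
    used = np.unique(triangles)
    remap = -np.ones(len(vertices), dtype=np.int64)
    remap[used] = np.arange(len(used))
    return vertices[used], remap[triangles]


def _cut_holes(vertices, triangles, rng, count, radius, extent):
    if count == 0 or radius == 0:
        return vertices, triangles
    centroids = vertices[triangles].mean(axis=1)
    keep = np.ones(len(triangles), dtype=bool)
    for _ in range(count):
        angle = rng.uniform(0, 2 * np.pi)
        rad = 0.7 * extent * np.sqrt(rng.uniform())
        cx, cy = rad * np.cos(angle), rad * np.sin(angle)
        d2 = (centroids[:, 0] - cx) ** 2 + (centroids[:, 1] - cy) ** 2
        keep &= d2 > radius**2
    return _drop_triangles(vertices, triangles, keep)


def _trim_border(vertices, triangles, trims):
    """Cut the four grid sides (x-min, x-max, y-min, y-max) by given margins."""
    if not np.any(np.asarray(trims) > 0):
        return vertices, triangles
    c = vertices[triangles].mean(axis=1)
    lo_x, hi_x = vertices[:, 0].min(), vertices[:, 0].max()
    lo_y, hi_y = vertices[:, 1].min(), vertices[:, 1].max()
    keep = (
        (c[:, 0] >= lo_x + trims[0])
        & (c[:, 0] <= hi_x - trims[1])
        & (c[:, 1] >= lo_y + trims[2])
        & (c[:, 1] <= hi_y - trims[3])
    )
    return _drop_triangles(vertices, triangles, keep)


def _finish_shell(vertices, triangles, rng, raggedness, noise_sigma):
    if raggedness > 0:
        mesh = TriMesh(vertices, triangles)
        b = boundary_vertices(mesh)
        vertices = vertices.copy()
        vertices[b] += rng.uniform(-raggedness, raggedness, size=(len(b), 3))
    if noise_sigma > 0:
        vertices = vertices + rng.normal(0, noise_sigma, size=vertices.shape)
    return TriMesh(vertices, triangles)


def generate_shell(params: ShellParams | None = None) -> TriMesh:
    """Generate one open bumpy dome shell; deterministic per seed."""
    params = params or ShellParams()
    rng = np.random.default_rng(params.seed)
    extent = 0.6 * params.dome_radius
    vertices, triangles = _dome(params)
    vertices = _radial_bumps(
        vertices, rng, params.bump_count, params.bump_amplitude,
        params.bump_width, 0.75 * extent,
    )
    vertices, triangles = _cut_holes(
        vertices, triangles, rng, params.hole_count, params.hole_radius, extent
    )
    return _finish_shell(vertices, triangles, rng, params.raggedness,
                         params.noise_sigma)


def random_rigid_transform(
    rng: np.random.Generator,
    max_rot_deg: float,
    max_trans: float,
    center: np.ndarray,
) -> RigidTransform:
    """Random rotation (uniform axis, angle <= max) about ``center`` plus a
    random translation of magnitude <= ``max_trans``."""
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.deg2rad(rng.uniform(0, max_rot_deg))
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    rot = np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    t = rng.uniform(0, max_trans) * direction
    return RigidTransform(rotation=rot, translation=center + t - rot @ center)


def generate_population(
    spec: PopulationSpec | None = None,
) -> tuple[list[TriMesh], list[RigidTransform]]:
    """Generate ``n_faces`` shells with shared base shape, per-face smooth
    variation and artifacts, each displaced by a recorded rigid transform.

    Returns the displaced meshes and the ground-truth transforms (the i-th
    mesh equals the i-th undisplaced shape mapped by the i-th transform).
    """
    spec = spec or PopulationSpec()
    base = spec.base
    rng = np.random.default_rng(spec.seed)
    extent = 0.6 * base.dome_radius

    base_vertices, base_triangles = _dome(base)
    base_rng = np.random.default_rng(base.seed)
    base_vertices = _radial_bumps(
        base_vertices, base_rng, base.bump_count, base.bump_amplitude,
        base.bump_width, 0.75 * extent,
    )
    center = base_vertices.mean(axis=0)

    meshes: list[TriMesh] = []
    truths: list[RigidTransform] = []
    for _ in range(spec.n_faces):
        v = _radial_bumps(
            base_vertices, rng, spec.variation_count, spec.variation_amplitude,
            spec.variation_width, 0.75 * extent,
        )
        tri = base_triangles
        trims = rng.uniform(0, spec.border_trim_max, size=4)
        v, tri = _trim_border(v, tri, trims)
        v, tri = _cut_holes(v, tri, rng, base.hole_count, base.hole_radius,
                            extent)
        shell = _finish_shell(v, tri, rng, base.raggedness, base.noise_sigma)
        t = random_rigid_transform(rng, spec.jitter_rot_deg, spec.jitter_trans,
                                   center)
        meshes.append(TriMesh(t.apply(shell.vertices), shell.triangles))
        truths.append(t)
    return meshes, truths
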