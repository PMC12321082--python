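"""Transform estimation, sub-sampling strategies, and ICP registration."""

import numpy as np
import pytest
from scipy import stats

from facesim import (
    DegeneratePairingError,
    ICPConfig,
    TriMesh,
    apply_transform,
    dist,
    estimate_transform,
    flat_grid,
    icp_register,
    subsample_curvature,
    subsample_random,
    subsample_uniform_grid,
)
from facesim.proximity import PairingSet
from facesim.registration import gaussian_curvature
from facesim.synthetic import ShellParams, generate_shell, random_rigid_transform


def make_pairing(x, y):
    return PairingSet(np.arange(len(x)), np.asarray(x, float),
                      np.asarray(y, float),
                      np.linalg.norm(np.asarray(x) - np.asarray(y), axis=1),
                      0, 0)


class TestEstimateTransform:
    def test_self_pairing_gives_identity(self, rng):
        x = rng.normal(0, 10, (50, 3))
        t = estimate_transform(make_pairing(x, x))
        np.testing.assert_allclose(t.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(t.translation, 0, atol=1e-12)

    def test_recovers_known_rotation_translation(self, rng):
        x = rng.normal(0, 10, (100, 3))
        angle = np.deg2rad(15)
        rot = np.array([[np.cos(angle), -np.sin(angle), 0],
                        [np.sin(angle), np.cos(angle), 0],
                        [0, 0, 1.0]])
        y = x @ rot.T + [1.0, 0.0, 0.0]
        t = estimate_transform(make_pairing(x, y))
        np.testing.assert_allclose(t.rotation, rot, atol=1e-9)
        np.testing.assert_allclose(t.translation, [1, 0, 0], atol=1e-9)

    def test_recovers_uniform_scale(self, rng):
        x = rng.normal(0, 10, (100, 3))
        t = estimate_transform(make_pairing(x, 1.4 * x), allow_scale=True)
        assert abs(t.scale - 1.4) < 1e-9

    def test_collinear_points_raise(self):
        x = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0.0]])
        with pytest.raises(DegeneratePairingError):
            estimate_transform(make_pairing(x, x + [0, 1, 0]))

    def test_too_few_pairs_raise(self):
        x = np.array([[0, 0, 0], [1, 0, 0.0]])
        with pytest.raises(DegeneratePairingError):
            estimate_transform(make_pairing(x, x))


class TestSubsampling:
    def test_random_n_equals_vertex_count_returns_all(self, small_shell):
        idx = subsample_random(small_shell, small_shell.n_vertices, seed=0)
        np.testing.assert_array_equal(idx, np.arange(small_shell.n_vertices))

    def test_random_deterministic_per_seed(self, small_shell):
        a = subsample_random(small_shell, 200, seed=7)
        b = subsample_random(small_shell, 200, seed=7)
        c = subsample_random(small_shell, 200, seed=8)
        np.testing.assert_array_equal(a, b)
        assert len(np.unique(a)) == 200
        assert not np.array_equal(a, c)

    def test_random_single_draw_uniform_chi_square(self):
        mesh = flat_grid(5)  # 25 vertices
        counts = np.zeros(25)
        for s in range(10_000):
            counts[subsample_random(mesh, 1, seed=s)[0]] += 1
        assert stats.chisquare(counts).pvalue > 0.01

    def test_uniform_grid_cell_count_near_target(self):
        mesh = flat_grid(10)  # 100 vertices in a regular plane
        idx = subsample_uniform_grid(mesh, 25, seed=0)
        assert 22 <= len(idx) <= 28
        assert len(np.unique(idx)) == len(idx)

    def test_uniform_grid_degenerate_spread(self):
        mesh = TriMesh(np.array([[0, 0, 0], [1e-12, 0, 0], [0, 1e-12, 0.0]]),
                       np.array([[0, 1, 2]]))
        idx = subsample_uniform_grid(mesh, 10, seed=0)
        assert 1 <= len(idx) <= 11

    def test_uniform_grid_n_above_count_returns_all(self, small_shell):
        idx = subsample_uniform_grid(small_shell, small_shell.n_vertices + 5,
                                     seed=0)
        assert len(idx) == small_shell.n_vertices

    def test_curvature_flat_interior_zero(self):
        mesh = flat_grid(10)
        curv = gaussian_curvature(mesh)
        interior = [i for i in range(100)
                    if 0 < i // 10 < 9 and 0 < i % 10 < 9]
        assert np.abs(curv[interior]).max() < 1e-9

    def test_curvature_icosphere_matches_analytic(self):
        import trimesh

        r = 20.0
        ico = trimesh.creation.icosphere(subdivisions=3, radius=r)
        mesh = TriMesh(np.asarray(ico.vertices), np.asarray(ico.faces))
        curv = gaussian_curvature(mesh)
        assert np.abs(curv - 1 / r**2).max() < 0.2 / r**2

    def test_curvature_sampling_finds_sharp_bumps(self):
        # five sharp bumps on a fine flat grid; the sheet's four corners also
        # carry a real angle deficit (pi/2 over a tiny area), so the top-9
        # must consist of the corners plus one vertex per bump apex
        mesh = flat_grid(41, 0.5)  # spans 20x20
        centers = np.array([[4, 4], [16, 4], [10, 10], [4, 16], [16, 16]],
                           float)
        v = mesh.vertices.copy()
        for c in centers:
            d2 = ((v[:, :2] - c) ** 2).sum(axis=1)
            v[:, 2] += 3.0 * np.exp(-d2 / (2 * 0.8**2))
        bumpy = TriMesh(v, mesh.triangles)
        picked = subsample_curvature(bumpy, 9)
        picked_xy = bumpy.vertices[picked][:, :2]
        for c in centers:
            assert np.min(np.linalg.norm(picked_xy - c, axis=1)) < 1.0

    def test_curvature_deterministic(self, small_shell):
        a = subsample_curvature(small_shell, 100)
        b = subsample_curvature(small_shell, 100)
        np.testing.assert_array_equal(a, b)


class TestICP:
    def test_identical_copy_converges_immediately(self, small_shell):
        res = icp_register(small_shell, small_shell, ICPConfig(seed=0))
        assert res.converged and res.iterations_run <= 2
        assert res.final_d_avg < 1e-6
        assert res.transform.rotation_angle() < 1e-9

    def test_known_transform_recovery(self, small_shell, rng):
        c = small_shell.vertices.mean(axis=0)
        t = random_rigid_transform(rng, 10, 5, c)
        moving = apply_transform(small_shell, t)
        res = icp_register(moving, small_shell, ICPConfig(seed=0))
        moved = apply_transform(moving, res.transform)
        assert dist(moved, small_shell) < 0.05
        comp = res.transform.compose(t)
        assert comp.rotation_angle() < 1e-3
        centroid_err = np.linalg.norm(comp.apply(c) - c)
        assert centroid_err < 1e-2

    def test_deterministic_given_seed(self, small_shell, rng):
        c = small_shell.vertices.mean(axis=0)
        t = random_rigid_transform(rng, 8, 4, c)
        moving = apply_transform(small_shell, t)
        r1 = icp_register(moving, small_shell, ICPConfig(seed=5))
        r2 = icp_register(moving, small_shell, ICPConfig(seed=5))
        np.testing.assert_array_equal(r1.transform.rotation,
                                      r2.transform.rotation)
        assert r1.history == r2.history

    def test_history_non_increasing_in_fixed_regime(self, small_shell, rng):
        c = small_shell.vertices.mean(axis=0)
        t = random_rigid_transform(rng, 10, 5, c)
        moving = apply_transform(small_shell, t)
        res = icp_register(moving, small_shell, ICPConfig(seed=0))
        h = res.history
        # from iteration 3 onward the crop regime is fixed
        assert all(h[i + 1] <= h[i] + 1e-6 for i in range(2, len(h) - 1))

    def test_zero_overlap_raises_meaningful_error(self):
        # with no overlap, either the cropped pairing empties (insufficient
        # overlap, naming the iteration) or the uncropped iteration's pairing
        # collapses onto the far border (degenerate pairing)
        a = flat_grid(6)
        b = flat_grid(6, origin=(100.0, 100.0))
        from facesim import InsufficientOverlapError

        with pytest.raises((InsufficientOverlapError, DegeneratePairingError)):
            icp_register(a, b, ICPConfig(seed=0, n_samples=10))
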