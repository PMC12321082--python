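"""Mesh data model, I/O round-trips, boundary topology, normals, transforms."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from facesim import (
    MeshError,
    MeshFormatError,
    RigidTransform,
    TriMesh,
    apply_transform,
    boundary_edges,
    flat_grid,
    generate_shell,
    load_mesh,
    save_mesh,
    vertex_normals,
)
from facesim.synthetic import ShellParams


def tetrahedron() -> TriMesh:
    v = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float)
    t = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])
    return TriMesh(v, t)


class TestTriMeshValidation:
    def test_rejects_out_of_range_index(self):
        with pytest.raises(MeshError):
            TriMesh(np.zeros((3, 3)), np.array([[0, 1, 5]]))

    def test_rejects_repeated_index(self):
        with pytest.raises(MeshError):
            TriMesh(np.zeros((3, 3)), np.array([[0, 1, 1]]))

    def test_rejects_non_unit_normals(self):
        v = np.eye(3)
        with pytest.raises(MeshError):
            TriMesh(v, np.array([[0, 1, 2]]), normals=2.0 * v)


class TestIO:
    def test_minimal_obj(self, tmp_path):
        p = tmp_path / "tri.obj"
        p.write_text("v 0 0 0\nv 1 0 0\nv 0 1 0\nf 1 2 3\n")
        m = load_mesh(p)
        assert m.n_vertices == 3 and m.n_triangles == 1

    def test_obj_quad_fan_triangulated(self, tmp_path):
        p = tmp_path / "quad.obj"
        p.write_text("v 0 0 0\nv 1 0 0\nv 1 1 0\nv 0 1 0\nf 1 2 3 4\n")
        m = load_mesh(p)
        assert m.n_vertices == 4 and m.n_triangles == 2
        # the two triangles share a diagonal edge
        shared = set(map(tuple, np.sort(m.triangles, axis=1)))
        assert len(shared) == 2

    @pytest.mark.parametrize("fmt", ["obj", "ply"])
    def test_roundtrip_indexed_formats(self, tmp_path, fmt):
        shell = generate_shell(ShellParams(resolution=16, seed=3))
        p = tmp_path / f"shell.{fmt}"
        save_mesh(shell, p)
        back = load_mesh(p)
        assert back.n_vertices == shell.n_vertices
        np.testing.assert_array_equal(back.triangles, shell.triangles)
        assert np.abs(back.vertices - shell.vertices).max() < 1e-6

    def test_roundtrip_stl(self, tmp_path):
        shell = generate_shell(ShellParams(resolution=12, seed=3))
        p = tmp_path / "shell.stl"
        save_mesh(shell, p)
        back = load_mesh(p)
        # STL de-indexes; merged vertex set must match the original surface
        assert back.n_triangles == shell.n_triangles
        # centroid sets should agree within float32 precision
        c0 = np.sort(shell.vertices[shell.triangles].mean(axis=1), axis=0)
        c1 = np.sort(back.vertices[back.triangles].mean(axis=1), axis=0)
        assert np.abs(c0 - c1).max() < 1e-3

    def test_refuses_empty_mesh(self, tmp_path):
        with pytest.raises(MeshError):
            save_mesh(TriMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=int)),
                      tmp_path / "empty.obj")

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(IOError):
            load_mesh(tmp_path / "nope.obj")

    def test_garbage_raises_format_error(self, tmp_path):
        p = tmp_path / "bad.obj"
        p.write_text("v 0 0\nf 1 2 99\n")
        with pytest.raises((MeshFormatError, IOError)):
            load_mesh(p)


class TestBoundaryEdges:
    def test_single_triangle_has_three(self):
        m = TriMesh(np.eye(3), np.array([[0, 1, 2]]))
        assert len(boundary_edges(m)) == 3

    def test_closed_tetrahedron_has_none(self):
        assert len(boundary_edges(tetrahedron())) == 0

    def test_planar_grid_count(self):
        # 10x10-cell grid: 200 triangles, 4 sides x 10 boundary edges
        m = flat_grid(11)
        assert m.n_triangles == 200
        assert len(boundary_edges(m)) == 40

    def test_matches_brute_force_tally(self, artifact_shell):
        from collections import defaultdict

        tally = defaultdict(int)
        for t in artifact_shell.triangles:
            for k in range(3):
                e = tuple(sorted((int(t[k]), int(t[(k + 1) % 3]))))
                tally[e] += 1
        expected = {e for e, c in tally.items() if c == 1}
        assert boundary_edges(artifact_shell) == expected


class TestWindingCheck:
    def test_consistent_grid_reports_zero(self):
        from facesim.mesh_core import inconsistent_winding_edges

        assert inconsistent_winding_edges(flat_grid(8)) == 0

    def test_flipped_triangle_reported(self):
        from facesim.mesh_core import inconsistent_winding_edges

        m = flat_grid(8)
        tris = m.triangles.copy()
        tris[0] = tris[0][::-1]  # reverse one triangle's winding
        flipped = TriMesh(m.vertices, tris)
        assert inconsistent_winding_edges(flipped) >= 1


class TestVertexNormals:
    def test_flat_grid_all_up(self):
        n = vertex_normals(flat_grid(8))
        np.testing.assert_allclose(n, np.tile([0.0, 0.0, 1.0], (64, 1)),
                                   atol=1e-12)

    def test_single_triangle_equals_face_normal(self):
        m = TriMesh(np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], float),
                    np.array([[0, 1, 2]]))
        n = vertex_normals(m)
        np.testing.assert_allclose(n, np.tile([0, 0, 1.0], (3, 1)), atol=1e-12)

    def test_icosphere_normals_radial(self):
        import trimesh

        ico = trimesh.creation.icosphere(subdivisions=3, radius=20.0)
        m = TriMesh(np.asarray(ico.vertices), np.asarray(ico.faces))
        n = vertex_normals(m)
        radial = m.vertices / np.linalg.norm(m.vertices, axis=1, keepdims=True)
        cos = np.einsum("ij,ij->i", n, radial)
        assert np.all(cos > np.cos(np.deg2rad(5.0)))


class TestRigidTransform:
    def test_identity_leaves_vertices(self, small_shell):
        out = apply_transform(small_shell, RigidTransform.identity())
        np.testing.assert_array_equal(out.vertices, small_shell.vertices)

    def test_translation_shifts_centroid(self, small_shell):
        t = RigidTransform(translation=np.array([1.0, 2.0, 3.0]))
        out = apply_transform(small_shell, t)
        np.testing.assert_allclose(
            out.vertices.mean(axis=0) - small_shell.vertices.mean(axis=0),
            [1, 2, 3], atol=1e-12)

    def test_inverse_composition_roundtrip(self, small_shell, rng):
        from facesim.synthetic import random_rigid_transform

        t = random_rigid_transform(rng, 30, 20, np.zeros(3))
        out = apply_transform(apply_transform(small_shell, t), t.inverse())
        assert np.abs(out.vertices - small_shell.vertices).max() < 1e-9

    def test_rejects_reflection(self):
        with pytest.raises(ValueError):
            RigidTransform(rotation=np.diag([1.0, 1.0, -1.0]))

    def test_matrix_roundtrip_with_scale(self, rng):
        from facesim.synthetic import random_rigid_transform

        t0 = random_rigid_transform(rng, 40, 5, np.zeros(3))
        t = RigidTransform(t0.rotation, t0.translation, scale=1.7)
        back = RigidTransform.from_matrix(t.matrix())
        np.testing.assert_allclose(back.rotation, t.rotation, atol=1e-12)
        assert abs(back.scale - t.scale) < 1e-12

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_rigidity_preserves_pairwise_distances(self, seed):
        rng = np.random.default_rng(seed)
        from facesim.synthetic import random_rigid_transform

        t = random_rigid_transform(rng, 90, 50, np.zeros(3))
        pts = rng.normal(0, 30, (20, 3))
        mapped = t.apply(pts)
        d0 = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        d1 = np.linalg.norm(mapped[:, None] - mapped[None, :], axis=2)
        assert np.abs(d0 - d1).max() < 1e-9
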