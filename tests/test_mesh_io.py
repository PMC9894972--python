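"""OBJ parsing, welding, winding, ring adjacency and vertex normals."""

import numpy as np
import pytest
import trimesh

from meshcurve import (
    MeshError,
    ObjParseError,
    TriangleMesh,
    build_adjacency,
    make_icosphere,
    make_plane,
    read_obj,
    vertex_normals,
    weld_vertices,
    write_obj,
)
from conftest import random_bumpy_mesh, random_rotation


def _write(tmp_path, text, name="m.obj"):
    p = tmp_path / name
    p.write_text(text)
    return p


MINIMAL = "v 0 0 0\nv 1 0 0\nv 0 1 0\nf 1 2 3\n"


class TestReadObj:
    def test_minimal_file(self, tmp_path):
        mesh = read_obj(_write(tmp_path, MINIMAL))
        assert mesh.n_vertices == 3
        assert mesh.n_faces == 1
        assert sorted(mesh.faces[0]) == [0, 1, 2]

    @pytest.mark.parametrize(
        "face_line", ["f 1//1 2//2 3//3", "f 1/4/1 2/5/2 3/6/3", "f 1/4 2/5 3/6"]
    )
    def test_slash_dialects_use_vertex_index_only(self, tmp_path, face_line):
        text = "v 0 0 0\nv 1 0 0\nv 0 1 0\nvn 0 0 1\nvt 0 0\n" + face_line + "\n"
        mesh = read_obj(_write(tmp_path, text))
        assert mesh.n_vertices == 3
        assert sorted(mesh.faces[0]) == [0, 1, 2]

    def test_quad_fan_triangulated(self, tmp_path):
        text = "v 0 0 0\nv 1 0 0\nv 1 1 0\nv 0 1 0\nf 1 2 3 4\n"
        mesh = read_obj(_write(tmp_path, text))
        assert mesh.n_faces == 2

    def test_out_of_range_index_reports_index_and_line(self, tmp_path):
        text = "v 0 0 0\nv 1 0 0\nv 0 1 0\nv 1 1 0\nf 1 2 5\n"
        with pytest.raises(ObjParseError, match=r"line 5.*index 5"):
            read_obj(_write(tmp_path, text))

    def test_non_numeric_coordinate_names_line(self, tmp_path):
        with pytest.raises(ObjParseError, match="line 2"):
            read_obj(_write(tmp_path, "v 0 0 0\nv a b c\nv 0 1 0\nf 1 2 3\n"))

    def test_face_with_two_vertices_rejected(self, tmp_path):
        with pytest.raises(ObjParseError, match="fewer than 3"):
            read_obj(_write(tmp_path, "v 0 0 0\nv 1 0 0\nv 0 1 0\nf 1 2\n"))

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_obj(tmp_path / "absent.obj")

    def test_empty_records_rejected(self, tmp_path):
        with pytest.raises(ObjParseError, match="at least one"):
            read_obj(_write(tmp_path, "# nothing\nv 0 0 0\n"))

    def test_duplicate_vertices_welded(self, tmp_path):
        # second vertex is a near-duplicate of the first (within 1e-6)
        text = (
            "v 0 0 0\nv 0 0 0.0000000001\nv 1 0 0\nv 0 1 0\n"
            "f 1 3 4\nf 2 4 3\n"
        )
        mesh = read_obj(_write(tmp_path, text))
        assert mesh.n_vertices == 3

    def test_agrees_with_trimesh_loader(self, tmp_path):
        """Independent parser cross-check on an icosphere round-trip."""
        mesh = make_icosphere(1)
        p = tmp_path / "ico.obj"
        write_obj(mesh, p)
        ours = read_obj(p, reorient=False)
        theirs = trimesh.load(str(p), process=False)
        np.testing.assert_allclose(ours.vertices, theirs.vertices, atol=1e-12)
        np.testing.assert_array_equal(ours.faces, theirs.faces)


class TestWriteObj:
    def test_round_trip_minimal(self, tmp_path):
        mesh = read_obj(_write(tmp_path, MINIMAL))
        out = tmp_path / "out.obj"
        write_obj(mesh, out)
        back = read_obj(out)
        np.testing.assert_allclose(back.vertices, mesh.vertices, atol=1e-6)
        np.testing.assert_array_equal(back.faces, mesh.faces)

    def test_round_trip_icosahedron_topology(self, tmp_path, icosahedron):
        out = tmp_path / "ico.obj"
        write_obj(icosahedron, out)
        back = read_obj(out)
        assert back.n_vertices == 12
        assert back.n_faces == 20
        np.testing.assert_allclose(back.vertices, icosahedron.vertices, atol=0)

    def test_empty_mesh_unconstructible(self):
        with pytest.raises(MeshError):
            TriangleMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=int))

    def test_unwritable_path(self, tmp_path, icosahedron):
        with pytest.raises(OSError):
            write_obj(icosahedron, tmp_path / "no" / "such" / "dir.obj")


class TestMeshValidation:
    def test_face_index_out_of_bounds(self):
        with pytest.raises(MeshError, match="out of range"):
            TriangleMesh(np.eye(3), [[0, 1, 3]])

    def test_repeated_index_in_face(self):
        with pytest.raises(MeshError, match="repeats"):
            TriangleMesh(np.eye(3), [[0, 1, 1]])

    def test_nan_coordinates_rejected(self):
        v = np.eye(3)
        v[0, 0] = np.nan
        with pytest.raises(MeshError, match="NaN"):
            TriangleMesh(v, [[0, 1, 2]])


def _bfs_neighbors(mesh: TriangleMesh, start: int, ring: int) -> set:
    """Plain breadth-first search oracle on the edge graph."""
    edges: dict[int, set] = {}
    for a, b, c in mesh.faces:
        for u, v in ((a, b), (b, c), (c, a)):
            edges.setdefault(int(u), set()).add(int(v))
            edges.setdefault(int(v), set()).add(int(u))
    seen = {start}
    frontier = {start}
    out: set = set()
    for _ in range(ring):
        frontier = {w for u in frontier for w in edges.get(u, ())} - seen
        seen |= frontier
        out |= frontier
    return out


class TestAdjacency:
    def test_tetrahedron_ring1_is_complete_graph(self, tetrahedron):
        for nb in build_adjacency(tetrahedron, 1):
            assert nb.m == 3

    @pytest.mark.parametrize("ring,expected_m", [(1, 5), (2, 10), (3, 11)])
    def test_icosahedron_rings_match_bfs(self, icosahedron, ring, expected_m):
        nbs = build_adjacency(icosahedron, ring)
        for nb in nbs:
            assert nb.m == expected_m
            assert nb.neighbor_indices.tolist() == sorted(
                _bfs_neighbors(icosahedron, nb.vertex_index, ring)
            )

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_mesh_matches_bfs_oracle(self, seed):
        mesh = random_bumpy_mesh(seed, n=8)
        for ring in (1, 2, 3):
            for nb in build_adjacency(mesh, ring):
                assert set(nb.neighbor_indices.tolist()) == _bfs_neighbors(
                    mesh, nb.vertex_index, ring
                )

    def test_ring1_symmetry_and_ring_monotonicity(self):
        mesh = random_bumpy_mesh(7, n=8)
        one = build_adjacency(mesh, 1)
        for nb in one:
            for j in nb.neighbor_indices:
                assert nb.vertex_index in one[j].neighbor_indices
        two = build_adjacency(mesh, 2)
        for a, b in zip(one, two):
            assert set(a.neighbor_indices) <= set(b.neighbor_indices)

    def test_isolated_vertex_flagged_with_zero_neighbors(self):
        v = np.vstack([np.eye(3), [[5.0, 5.0, 5.0]]])
        mesh = TriangleMesh(v, [[0, 1, 2]])
        assert mesh.isolated_vertices()[3]
        assert build_adjacency(mesh, 2)[3].m == 0


class TestVertexNormals:
    def test_planar_grid_normals_are_plus_z(self, plane_grid):
        n = vertex_normals(plane_grid)
        np.testing.assert_allclose(n, np.tile([0.0, 0.0, 1.0], (plane_grid.n_vertices, 1)), atol=1e-12)

    @pytest.mark.parametrize("rule", ["area", "uniform", "angle"])
    def test_unit_length(self, rule):
        mesh = random_bumpy_mesh(3, n=8)
        n = vertex_normals(mesh, rule)
        np.testing.assert_allclose(np.linalg.norm(n, axis=1), 1.0, atol=1e-9)

    def test_icosphere_normals_radial_and_refining(self):
        """Normals track the radial direction, tighter under refinement."""
        prev = None
        for sub in (2, 3, 4):
            sphere = make_icosphere(sub)
            n = vertex_normals(sphere)
            radial = sphere.vertices / np.linalg.norm(sphere.vertices, axis=1)[:, None]
            angles = np.arccos(np.clip(np.einsum("ij,ij->i", n, radial), -1, 1))
            worst = angles.max()
            assert worst < 0.025  # within ~1.4 degrees even at the coarse level
            if prev is not None:
                assert worst < prev
            prev = worst

    def test_zero_area_sliver_does_not_change_normals(self, plane_grid):
        base = vertex_normals(plane_grid)
        # vertices 0, 1, 2 of the grid row are exactly collinear: zero area
        f = np.vstack([plane_grid.faces, [[0, 1, 2]]])
        with_sliver = TriangleMesh(plane_grid.vertices, f)
        n = vertex_normals(with_sliver)
        np.testing.assert_allclose(n, base, atol=1e-12)

    def test_rotation_equivariance(self):
        mesh = random_bumpy_mesh(5, n=8)
        rot = random_rotation(11)
        n0 = vertex_normals(mesh)
        n1 = vertex_normals(TriangleMesh(mesh.vertices @ rot.T, mesh.faces))
        np.testing.assert_allclose(n1, n0 @ rot.T, atol=1e-9)

    def test_scale_invariance(self):
        mesh = random_bumpy_mesh(6, n=8)
        n0 = vertex_normals(mesh)
        n1 = vertex_normals(TriangleMesh(37.5 * mesh.vertices, mesh.faces))
        np.testing.assert_allclose(n1, n0, atol=1e-12)


class TestWeld:
    def test_merges_close_and_keeps_far(self):
        v = np.array([[0, 0, 0], [1e-9, 0, 0], [1, 0, 0], [0, 1, 0]], dtype=float)
        f = np.array([[0, 2, 3], [1, 3, 2]])
        nv, nf, imap = weld_vertices(v, f, 1e-6)
        assert nv.shape[0] == 3
        assert imap[0] == imap[1]
        assert nf.shape[0] == 2

    def test_degenerate_faces_dropped(self):
        v = np.array([[0, 0, 0], [1e-9, 0, 0], [1, 0, 0]], dtype=float)
        f = np.array([[0, 1, 2]])
        _, nf, _ = weld_vertices(v, f, 1e-6)
        assert nf.shape[0] == 0
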