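"""Triangle-mesh I/O and topology.

Reads and writes Wavefront OBJ surface meshes (the interchange format the
upstream CT-to-surface conversion produces) and builds the two structures
every downstream computation needs: ring neighborhoods on the edge graph
("range" in the curvature literature) and per-vertex unit normals, which
together define the tangent plane at each vertex.

Indices are 0-based internally and 1-based on disk, per the OBJ standard.
Vertices closer than a weld tolerance are merged on load because
CT-derived OBJ exports commonly contain duplicated vertices; faces made
degenerate by welding are dropped. Isolated vertices (incident to no face)
are retained in the mesh but excluded from all downstream statistics.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.spatial import cKDTree

__all__ = [
    "MeshError",
    "ObjParseError",
    "TriangleMesh",
    "VertexNeighborhood",
    "DEFAULT_WELD_TOLERANCE",
    "NORMAL_RULES",
    "read_obj",
    "write_obj",
    "weld_vertices",
    "orient_faces",
    "build_adjacency",
    "ring_neighbors",
    "vertex_normals",
    "nearest_vertex",
]

DEFAULT_WELD_TOLERANCE = 1e-6

#: Supported vertex-normal averaging rules.
NORMAL_RULES = ("area", "uniform", "angle")


class MeshError(ValueError):
    """Invalid mesh content or topology."""


class ObjParseError(MeshError):
    """Malformed OBJ input; the message names the offending line."""


@dataclass(frozen=True)
class TriangleMesh:
    """An indexed triangle mesh: ``vertices`` (n, 3) float, ``faces`` (m, 3) int.

    Coordinates are in mesh units (nominally mm for CT-derived surfaces).
    Construction validates index bounds, face non-degeneracy and coordinate
    finiteness; the arrays are frozen read-only.
    """

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=np.float64)
        f = np.asarray(self.faces, dtype=np.int64)
        if v.ndim != 2 or v.shape[1] != 3:
            raise MeshError(f"vertices must be (n, 3), got {v.shape}")
        if f.ndim != 2 or f.shape[1] != 3:
            raise MeshError(f"faces must be (m, 3), got {f.shape}")
        if v.shape[0] < 3 or f.shape[0] < 1:
            raise MeshError("mesh needs at least 3 vertices and 1 face")
        if not np.all(np.isfinite(v)):
            raise MeshError("vertex coordinates contain NaN or inf")
        if f.min(initial=0) < 0 or f.max(initial=-1) >= v.shape[0]:
            raise MeshError("face index out of range [0, n_vertices)")
        same = (f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])
        if np.any(same):
            raise MeshError(
                f"face {int(np.flatnonzero(same)[0])} repeats a vertex index"
            )
        v.setflags(write=False)
        f.setflags(write=False)
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def n_faces(self) -> int:
        return self.faces.shape[0]

    def face_areas(self) -> np.ndarray:
        tri = self.vertices[self.faces]
        cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        return 0.5 * np.linalg.norm(cross, axis=1)

    def isolated_vertices(self) -> np.ndarray:
        """Boolean mask of vertices incident to no face."""
        mask = np.ones(self.n_vertices, dtype=bool)
        mask[np.unique(self.faces)] = False
        return mask

    def boundary_vertices(self) -> np.ndarray:
        """Boolean mask of vertices on an open edge (edge with one incident face)."""
        e = np.sort(
            self.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1
        )
        edges, counts = np.unique(e, axis=0, return_counts=True)
        open_edges = edges[counts == 1]
        mask = np.zeros(self.n_vertices, dtype=bool)
        mask[open_edges.ravel()] = True
        return mask


@dataclass(frozen=True)
class VertexNeighborhood:
    """Vertices within ``ring`` edge-graph steps of ``vertex_index`` (excl. itself)."""

    vertex_index: int
    ring: int
    neighbor_indices: np.ndarray  # sorted, unique
    m: int = field(init=False)

    def __post_init__(self) -> None:
        idx = np.asarray(self.neighbor_indices, dtype=np.int64)
        idx = np.unique(idx)
        if self.vertex_index in idx:
            raise MeshError("a vertex cannot neighbor itself")
        idx.setflags(write=False)
        object.__setattr__(self, "neighbor_indices", idx)
        object.__setattr__(self, "m", int(idx.size))


# ---------------------------------------------------------------------------
# OBJ reading / writing
# ---------------------------------------------------------------------------

def read_obj(
    path: str | os.PathLike,
    *,
    weld_tolerance: float | None = DEFAULT_WELD_TOLERANCE,
    reorient: bool = True,
) -> TriangleMesh:
    """Read a Wavefront OBJ triangle mesh.

    ``f`` records with texture/normal slashes (``f a/b/c ...``) use the vertex
    index only; polygons with more than 3 vertices are fan-triangulated;
    ``vn``, ``vt``, comments, groups and material statements are ignored.
    OBJ's 1-based indices become 0-based. Vertices closer than
    ``weld_tolerance`` are merged (pass ``None`` to disable); face winding is
    made consistent and outward-facing unless ``reorient=False``.
    """
    verts: list[list[float]] = []
    polys: list[tuple[int, list[int]]] = []  # (line number, 0-based indices)
    with open(path, "r", encoding="utf-8", errors="replace") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            tag = tokens[0]
            if tag == "v":
                if len(tokens) < 4:
                    raise ObjParseError(
                        f"{path}, line {lineno}: vertex needs 3 coordinates: {line!r}"
                    )
                try:
                    verts.append([float(t) for t in tokens[1:4]])
                except ValueError as exc:
                    raise ObjParseError(
                        f"{path}, line {lineno}: non-numeric coordinate in {line!r}"
                    ) from exc
            elif tag == "f":
                refs = tokens[1:]
                if len(refs) < 3:
                    raise ObjParseError(
                        f"{path}, line {lineno}: face with fewer than 3 vertices"
                    )
                idx = []
                for ref in refs:
                    head = ref.split("/", 1)[0]
                    try:
                        k = int(head)
                    except ValueError as exc:
                        raise ObjParseError(
                            f"{path}, line {lineno}: bad face index {ref!r}"
                        ) from exc
                    if k == 0:
                        raise ObjParseError(
                            f"{path}, line {lineno}: OBJ indices are 1-based, got 0"
                        )
                    idx.append(k - 1 if k > 0 else len(verts) + k)
                polys.append((lineno, idx))
            # vn / vt / usemtl / mtllib / g / o / s: ignored
    if not verts or not polys:
        raise ObjParseError(f"{path}: needs at least one 'v' and one 'f' record")

    n = len(verts)
    faces: list[list[int]] = []
    for lineno, idx in polys:
        for k in idx:
            if not 0 <= k < n:
                raise ObjParseError(
                    f"{path}, line {lineno}: face index {k + 1} out of range "
                    f"(mesh has {n} vertices)"
                )
        for a, b in zip(idx[1:-1], idx[2:]):  # fan triangulation
            faces.append([idx[0], a, b])

    vertices = np.asarray(verts, dtype=np.float64)
    face_arr = np.asarray(faces, dtype=np.int64)
    if weld_tolerance is not None:
        vertices, face_arr, _ = weld_vertices(vertices, face_arr, weld_tolerance)
    mesh = TriangleMesh(vertices, face_arr)
    if reorient:
        mesh = orient_faces(mesh)
    return mesh


def write_obj(mesh: TriangleMesh, path: str | os.PathLike) -> None:
    """Write ``v`` then ``f`` records with 1-based indices.

    Coordinates are printed with enough digits that a read-back reproduces
    them to double precision; faces round-trip exactly.
    """
    if not isinstance(mesh, TriangleMesh):
        raise MeshError("write_obj expects a TriangleMesh")
    with open(path, "w", encoding="utf-8") as fh:
        for x, y, z in mesh.vertices:
            fh.write(f"v {x:.17g} {y:.17g} {z:.17g}\n")
        for a, b, c in mesh.faces + 1:
            fh.write(f"f {a} {b} {c}\n")


def weld_vertices(
    vertices: np.ndarray, faces: np.ndarray, tolerance: float = DEFAULT_WELD_TOLERANCE
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Merge vertices closer than ``tolerance`` (grid quantization).

    Returns (vertices, faces, index_map) where ``index_map[old] -> new``.
    Faces that collapse to fewer than 3 distinct vertices are dropped.
    """
    if tolerance <= 0:
        raise MeshError("weld tolerance must be positive")
    keys = np.round(np.asarray(vertices, dtype=np.float64) / tolerance).astype(np.int64)
    _, first, inverse = np.unique(keys, axis=0, return_index=True, return_inverse=True)
    # keep the first occurrence's exact coordinates, preserving input order
    order = np.argsort(first, kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(order.size)
    new_vertices = np.asarray(vertices)[first[order]]
    index_map = rank[inverse]
    new_faces = index_map[np.asarray(faces, dtype=np.int64)]
    ok = (
        (new_faces[:, 0] != new_faces[:, 1])
        & (new_faces[:, 1] != new_faces[:, 2])
        & (new_faces[:, 0] != new_faces[:, 2])
    )
    return new_vertices, new_faces[ok], index_map


def orient_faces(mesh: TriangleMesh) -> TriangleMesh:
    """Make winding consistent across shared edges, outward by majority vote.

    Winding is propagated component-by-component over the face adjacency
    graph (faces sharing an edge must traverse it in opposite directions);
    each component is then flipped, if needed, so that face normals point
    away from the mesh centroid on average.
    """
    faces = mesh.faces.copy()
    nf = faces.shape[0]
    # edge (sorted pair) -> incident face list
    e = np.sort(faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
    face_of_edge = np.repeat(np.arange(nf), 3)
    order = np.lexsort((e[:, 1], e[:, 0]))
    e_sorted, f_sorted = e[order], face_of_edge[order]
    same = np.all(e_sorted[1:] == e_sorted[:-1], axis=1)
    pairs = np.stack([f_sorted[:-1][same], f_sorted[1:][same]], axis=1)

    adj: list[list[int]] = [[] for _ in range(nf)]
    for a, b in pairs:
        adj[a].append(b)
        adj[b].append(a)

    def directed_edges(face: np.ndarray) -> set[tuple[int, int]]:
        a, b, c = face
        return {(a, b), (b, c), (c, a)}

    visited = np.zeros(nf, dtype=bool)
    centroid = mesh.vertices.mean(axis=0)
    for start in range(nf):
        if visited[start]:
            continue
        component = [start]
        visited[start] = True
        stack = [start]
        while stack:
            cur = stack.pop()
            cur_dir = directed_edges(faces[cur])
            for nxt in adj[cur]:
                if visited[nxt]:
                    continue
                # consistent winding: no directed edge may be shared
                if directed_edges(faces[nxt]) & cur_dir:
                    faces[nxt, 1], faces[nxt, 2] = faces[nxt, 2], faces[nxt, 1]
                visited[nxt] = True
                component.append(nxt)
                stack.append(nxt)
        comp = np.asarray(component)
        tri = mesh.vertices[faces[comp]]
        normals = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        outward = np.einsum("ij,ij->i", normals, tri.mean(axis=1) - centroid)
        if outward.sum() < 0:
            faces[comp, 1], faces[comp, 2] = faces[comp, 2], faces[comp, 1]
    return TriangleMesh(mesh.vertices, faces)


# ---------------------------------------------------------------------------
# Adjacency / ring neighborhoods
# ---------------------------------------------------------------------------

def _edge_graph(mesh: TriangleMesh) -> sparse.csr_matrix:
    f = mesh.faces
    rows = np.concatenate([f[:, 0], f[:, 1], f[:, 1], f[:, 2], f[:, 2], f[:, 0]])
    cols = np.concatenate([f[:, 1], f[:, 0], f[:, 2], f[:, 1], f[:, 0], f[:, 2]])
    data = np.ones(rows.size, dtype=np.float64)
    a = sparse.coo_matrix((data, (rows, cols)), shape=(mesh.n_vertices,) * 2).tocsr()
    a.data[:] = 1.0
    return a


def ring_neighbors(mesh: TriangleMesh, ring: int) -> sparse.csr_matrix:
    """CSR matrix with (i, j) nonzero iff 1 <= graph_distance(i, j) <= ring."""
    if ring < 1:
        raise MeshError("ring must be >= 1")
    a = _edge_graph(mesh)
    reach = a.copy()
    frontier = a
    for _ in range(ring - 1):
        frontier = frontier @ a
        frontier.data[:] = 1.0
        reach = reach + frontier
        reach.data[:] = 1.0
    reach = sparse.csr_matrix(reach)
    reach.setdiag(0)
    reach.eliminate_zeros()
    reach.sort_indices()
    return reach


def build_adjacency(mesh: TriangleMesh, ring: int) -> list[VertexNeighborhood]:
    """Ring neighborhood of every vertex; isolated vertices get m = 0."""
    reach = ring_neighbors(mesh, ring)
    out = []
    for i in range(mesh.n_vertices):
        nbrs = reach.indices[reach.indptr[i]:reach.indptr[i + 1]]
        out.append(VertexNeighborhood(i, ring, nbrs))
    return out


# ---------------------------------------------------------------------------
# Vertex normals
# ---------------------------------------------------------------------------

def vertex_normals(mesh: TriangleMesh, rule: str = "area") -> np.ndarray:
    """Per-vertex unit normals, (n, 3).

    ``rule`` selects the face-normal averaging weight:

    - ``"area"`` (default): area-weighted average of incident face normals,
    - ``"uniform"``: plain average of incident unit face normals,
    - ``"angle"``: weighted by the face's interior angle at the vertex.

    Faces with zero area are skipped. A vertex all of whose incident faces
    are degenerate raises; isolated vertices get a NaN normal (they are
    excluded from downstream statistics).
    """
    if rule not in NORMAL_RULES:
        raise MeshError(f"unknown normal rule {rule!r}; choose from {NORMAL_RULES}")
    tri = mesh.vertices[mesh.faces]
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])  # 2A * n_f
    twice_area = np.linalg.norm(cross, axis=1)
    scale = max(float(np.abs(mesh.vertices).max()), 1.0)
    good = twice_area > 1e-14 * scale * scale

    acc = np.zeros((mesh.n_vertices, 3))
    if rule == "area":
        contrib = cross[good]
        weights = np.ones(int(good.sum()))
    else:
        unit = cross[good] / twice_area[good, None]
        contrib = unit
        weights = None
    for corner in range(3):
        vids = mesh.faces[good, corner]
        if rule == "angle":
            p = tri[good, corner]
            q = tri[good, (corner + 1) % 3]
            r = tri[good, (corner + 2) % 3]
            u, w = q - p, r - p
            cosang = np.einsum("ij,ij->i", u, w) / (
                np.linalg.norm(u, axis=1) * np.linalg.norm(w, axis=1)
            )
            ang = np.arccos(np.clip(cosang, -1.0, 1.0))
            np.add.at(acc, vids, contrib * ang[:, None])
        else:
            np.add.at(acc, vids, contrib)

    norms = np.linalg.norm(acc, axis=1)
    isolated = mesh.isolated_vertices()
    bad = (norms < 1e-300) & ~isolated
    if np.any(bad):
        # distinguish "all incident faces degenerate" from cancelation
        incident_good = np.zeros(mesh.n_vertices, dtype=bool)
        incident_good[np.unique(mesh.faces[good])] = True
        dead = bad & ~incident_good
        if np.any(dead):
            raise MeshError(
                f"vertex {int(np.flatnonzero(dead)[0])}: all incident faces degenerate"
            )
        raise MeshError(
            f"vertex {int(np.flatnonzero(bad)[0])}: face normals cancel; "
            "mesh winding is inconsistent (run orient_faces)"
        )
    out = np.full((mesh.n_vertices, 3), np.nan)
    ok = ~isolated
    out[ok] = acc[ok] / norms[ok, None]
    return out


def nearest_vertex(mesh: TriangleMesh, point: np.ndarray) -> int:
    """Index of the mesh vertex closest to ``point`` (Euclidean)."""
    tree = cKDTree(mesh.vertices)
    return int(tree.query(np.asarray(point, dtype=float))[1])
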