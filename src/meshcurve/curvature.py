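"""Per-vertex discrete curvature approximation.

The statistic is the mean, over a vertex's ring neighborhood, of
``|sin θ_j|`` where ``θ_j`` is the angle between the edge to neighbor
``X_j`` and the tangent plane ``P`` at the reference vertex ``V_i``
(the plane through ``V_i`` perpendicular to the vertex normal ``N``):

    d_j     = X_j · N − V_i · N          (signed distance of X_j from P)
    sin θ_j = |d_j| / ‖X_j − V_i‖
    C(V_i)  = (1/m) Σ_j sin θ_j

``C`` is dimensionless, lies in [0, 1] (Cauchy–Schwarz), is invariant
under uniform scaling and rigid motion, and measures how sharply the
surface bends away from its tangent plane: 0 on a plane, → 1 at a
needle-like spike. On a sphere, a vertex whose ring neighbors all sit at
angular distance φ has C = sin(φ/2) exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh_io import MeshError, TriangleMesh, ring_neighbors, vertex_normals

__all__ = [
    "CurvatureField",
    "signed_plane_distance",
    "sin_theta",
    "discrete_curvature",
]

#: edge lengths below this (in mesh units) are treated as welded duplicates
_ZERO_EDGE = 1e-12


@dataclass(frozen=True)
class CurvatureField:
    """Per-vertex curvature with the provenance needed to reproduce it.

    ``values[i]`` is NaN for vertices with no neighbors (m = 0) — an
    explicit "undefined" marker, never a number. ``boundary`` flags
    vertices on open mesh edges so users can exclude them (ROI-cropped
    exports are open; thresholded CT surfaces are typically closed).
    """

    values: np.ndarray        # (n,) float, NaN = undefined
    m: np.ndarray             # (n,) int, neighbors used per vertex
    ring: int
    normal_rule: str
    boundary: np.ndarray      # (n,) bool
    dropped_zero_edges: int = 0

    @property
    def defined(self) -> np.ndarray:
        return self.m > 0

    def defined_values(self, indices: np.ndarray | None = None) -> np.ndarray:
        """Curvature values (optionally restricted to ``indices``), NaNs dropped."""
        vals = self.values if indices is None else self.values[np.asarray(indices)]
        return vals[~np.isnan(vals)]


def signed_plane_distance(X, V, N) -> float:
    """Signed distance of point ``X`` from the plane through ``V`` with unit normal ``N``."""
    X, V, N = (np.asarray(a, dtype=float) for a in (X, V, N))
    if abs(np.linalg.norm(N) - 1.0) > 1e-9:
        raise ValueError("N must be a unit vector (caller normalizes)")
    # einsum keeps the accumulation order identical to the vectorized path
    return float(np.einsum("i,i->", X, N) - np.einsum("i,i->", V, N))


def sin_theta(X, V, N) -> float:
    """|sin| of the angle between edge V→X and the tangent plane at V."""
    X, V = np.asarray(X, dtype=float), np.asarray(V, dtype=float)
    gap = X - V
    edge = float(np.sqrt(np.einsum("i,i->", gap, gap)))
    if edge < _ZERO_EDGE:
        raise ValueError("X coincides with V (zero-length edge); exclude this neighbor")
    s = abs(signed_plane_distance(X, V, N)) / edge
    return min(s, 1.0)


def discrete_curvature(
    mesh: TriangleMesh,
    ring: int = 3,
    normals: np.ndarray | None = None,
    *,
    normal_rule: str = "area",
) -> CurvatureField:
    """Discrete curvature of every vertex over its ``ring`` neighborhood.

    Vectorized over all (vertex, neighbor) pairs; deterministic and
    independent of neighbor enumeration order. ``normals`` may be supplied
    (unit vectors, one per vertex); otherwise they are computed with
    ``normal_rule``. Neighbors at zero edge length (welded duplicates that
    survived) are dropped from ``m`` rather than failing the vertex; the
    count of dropped pairs is recorded.
    """
    if normals is None:
        normals = vertex_normals(mesh, normal_rule)
    else:
        normals = np.asarray(normals, dtype=float)
        if normals.shape != (mesh.n_vertices, 3):
            raise MeshError("normals must be (n_vertices, 3)")
        lens = np.linalg.norm(normals, axis=1)
        live = ~np.isnan(lens)
        if np.any(np.abs(lens[live] - 1.0) > 1e-9):
            raise MeshError("normals must be unit length")

    reach = ring_neighbors(mesh, ring)
    rows = np.repeat(np.arange(mesh.n_vertices), np.diff(reach.indptr))
    cols = reach.indices
    diff = mesh.vertices[cols] - mesh.vertices[rows]
    edge = np.sqrt(np.einsum("ij,ij->i", diff, diff))

    keep = edge >= _ZERO_EDGE
    dropped = int(np.size(keep) - np.count_nonzero(keep))
    rows, cols, diff, edge = rows[keep], cols[keep], diff[keep], edge[keep]

    # d = X·N − V·N, evaluated exactly as written so the scalar path agrees
    d = np.einsum("ij,ij->i", mesh.vertices[cols], normals[rows]) - np.einsum(
        "ij,ij->i", mesh.vertices[rows], normals[rows]
    )
    s = np.minimum(np.abs(d) / edge, 1.0)

    n = mesh.n_vertices
    sums = np.bincount(rows, weights=s, minlength=n)
    counts = np.bincount(rows, minlength=n)
    values = np.full(n, np.nan)
    ok = counts > 0
    values[ok] = sums[ok] / counts[ok]
    return CurvatureField(
        values=values,
        m=counts.astype(np.int64),
        ring=ring,
        normal_rule=normal_rule,
        boundary=mesh.boundary_vertices(),
        dropped_zero_edges=dropped,
    )
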