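"""Region-of-interest selection and contralateral mirroring.

An ROI is the set of mesh vertices inside a Euclidean ball around a
user-supplied center (coordinates stand in for interactive picking). For
bilateral comparison the ROI is reflected across a mid-sagittal plane —
supplied explicitly or estimated from the mesh's reflective symmetry —
and the two regions' extents are equalized automatically: the larger
region's radius is shrunk by bisection until the summed face areas agree
to within 2%. Equalization only ever shrinks a region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .mesh_io import MeshError, TriangleMesh

__all__ = [
    "ROIError",
    "ROISelection",
    "MirrorPlane",
    "select_roi",
    "mirror_point",
    "mirror_roi",
    "estimate_sagittal_plane",
    "AREA_TOLERANCE",
]

#: relative area mismatch allowed between the two sides after equalization
AREA_TOLERANCE = 0.02
#: bisection stops when the radius interval is below this (mesh units)
RADIUS_RESOLUTION = 1e-3

SIDES = ("affected", "unaffected")


class ROIError(ValueError):
    """Empty or inconsistent region selection."""


@dataclass(frozen=True)
class ROISelection:
    """A labeled ball selection: vertices within ``radius`` of ``center``.

    ``selected_area`` is the summed area of faces whose three vertices are
    all selected (robust to dangling vertices).
    """

    label: str
    side: str
    center: np.ndarray
    radius: float
    vertex_indices: np.ndarray  # sorted
    selected_area: float

    def __post_init__(self) -> None:
        if self.side not in SIDES:
            raise ROIError(f"side must be one of {SIDES}, got {self.side!r}")
        if self.radius <= 0:
            raise ROIError("radius must be positive")
        c = np.asarray(self.center, dtype=float).reshape(3)
        idx = np.unique(np.asarray(self.vertex_indices, dtype=np.int64))
        c.setflags(write=False)
        idx.setflags(write=False)
        object.__setattr__(self, "center", c)
        object.__setattr__(self, "vertex_indices", idx)

    @property
    def n_vertices(self) -> int:
        return int(self.vertex_indices.size)


@dataclass(frozen=True)
class MirrorPlane:
    """A plane given by a point on it and a unit normal."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.point, dtype=float).reshape(3)
        n = np.asarray(self.normal, dtype=float).reshape(3)
        length = np.linalg.norm(n)
        if length < 1e-12:
            raise MeshError("mirror plane normal must be nonzero")
        n = n / length
        p.setflags(write=False)
        n.setflags(write=False)
        object.__setattr__(self, "point", p)
        object.__setattr__(self, "normal", n)


def _selection_area(mesh: TriangleMesh, indices: np.ndarray) -> float:
    inside = np.zeros(mesh.n_vertices, dtype=bool)
    inside[indices] = True
    full = inside[mesh.faces].all(axis=1)
    return float(mesh.face_areas()[full].sum())


def select_roi(
    mesh: TriangleMesh,
    center,
    radius: float,
    label: str = "roi",
    side: str = "affected",
    *,
    _tree: cKDTree | None = None,
) -> ROISelection:
    """All vertices within Euclidean distance ``radius`` of ``center``."""
    if radius <= 0:
        raise ROIError("radius must be positive")
    center = np.asarray(center, dtype=float).reshape(3)
    tree = _tree if _tree is not None else cKDTree(mesh.vertices)
    idx = np.asarray(tree.query_ball_point(center, radius), dtype=np.int64)
    if idx.size == 0:
        raise ROIError(
            f"ROI {label!r}: no vertex within {radius} of {center.tolist()}; "
            "enlarge the radius or correct the center"
        )
    idx.sort()
    return ROISelection(
        label=label,
        side=side,
        center=center,
        radius=float(radius),
        vertex_indices=idx,
        selected_area=_selection_area(mesh, idx),
    )


def mirror_point(p, plane: MirrorPlane) -> np.ndarray:
    """Reflect ``p`` (a point or an (n, 3) array of points) across the plane."""
    p = np.asarray(p, dtype=float)
    d = (p - plane.point) @ plane.normal
    return p - 2.0 * np.multiply.outer(d, plane.normal)


def _shrink_to_area(
    mesh: TriangleMesh, roi: ROISelection, target: float, tree: cKDTree
) -> ROISelection:
    """Shrink roi's radius by bisection until its area best matches ``target``."""
    lo, hi = 0.0, roi.radius
    best = roi
    while hi - lo > RADIUS_RESOLUTION:
        mid = 0.5 * (lo + hi)
        try:
            cand = select_roi(
                mesh, roi.center, mid, roi.label, roi.side, _tree=tree
            )
        except ROIError:
            lo = mid
            continue
        if cand.selected_area > target:
            hi = mid
        else:
            lo = mid
        if abs(cand.selected_area - target) < abs(best.selected_area - target):
            best = cand
    return best


def mirror_roi(
    mesh: TriangleMesh,
    roi: ROISelection,
    plane: MirrorPlane,
    *,
    equalize: bool = True,
    area_tolerance: float = AREA_TOLERANCE,
) -> tuple[ROISelection, ROISelection]:
    """Contralateral region of equal extent.

    Reflects the ROI center across ``plane`` and selects with the same
    radius; then, if the two selected areas differ by more than
    ``area_tolerance`` (relative to the larger), shrinks the larger
    region's radius by bisection. Returns ``(source, mirrored)`` — either
    may have been shrunk, never grown. The mirrored side flag is flipped.
    """
    if roi.n_vertices == 0:
        raise ROIError("source ROI is empty")
    mcenter = mirror_point(roi.center, plane)
    tree = cKDTree(mesh.vertices)
    nearest = tree.query(mcenter)[0]
    if nearest > roi.radius:
        raise ROIError(
            f"mirrored center {mcenter.tolist()} is {nearest:.3g} mesh units from "
            "the nearest vertex (> radius); the mirror plane is likely wrong"
        )
    other = "unaffected" if roi.side == "affected" else "affected"
    mirrored = select_roi(mesh, mcenter, roi.radius, roi.label, other, _tree=tree)
    if not equalize:
        return roi, mirrored
    a, b = roi.selected_area, mirrored.selected_area
    larger = max(a, b)
    if larger > 0 and abs(a - b) / larger > area_tolerance:
        if a > b:
            roi = _shrink_to_area(mesh, roi, b, tree)
        else:
            mirrored = _shrink_to_area(mesh, mirrored, a, tree)
    return roi, mirrored


def estimate_sagittal_plane(
    mesh: TriangleMesh, override: MirrorPlane | None = None
) -> MirrorPlane:
    """Mid-plane of bilateral symmetry.

    Candidate normals are the three principal axes of the vertex
    covariance; the plane through the centroid whose reflection minimizes
    the mean nearest-neighbor distance between the mesh and its mirror
    image wins. A user-supplied ``override`` is returned unchanged
    (anthropometric landmark placement stays the user's call).
    """
    if override is not None:
        return override
    if mesh.n_vertices < 10:
        raise MeshError("need at least 10 vertices to estimate a symmetry plane")
    centroid = mesh.vertices.mean(axis=0)
    cov = np.cov((mesh.vertices - centroid).T)
    evals, evecs = np.linalg.eigh(cov)
    if evals[0] < 1e-10 * max(evals[-1], 1e-300):
        raise MeshError("mesh is degenerate (coplanar); symmetry plane is ambiguous")
    tree = cKDTree(mesh.vertices)
    best = None
    for k in range(3):
        plane = MirrorPlane(centroid, evecs[:, k])
        reflected = mirror_point(mesh.vertices, plane)
        score = float(tree.query(reflected)[0].mean())
        if best is None or score < best[0]:
            best = (score, plane)
    plane = best[1]
    # sign convention: largest-magnitude component positive
    n = plane.normal
    if n[np.argmax(np.abs(n))] < 0:
        plane = MirrorPlane(plane.point, -n)
    return plane
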