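"""End-to-end workflows tying the pipeline stages together.

These are the unit analyses the CLI (and the phantom studies) run:
curvature → ROI → histogram → weighted average, the pre/post fracture
comparison, and the bilateral affected/unaffected similarity quartet.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .curvature import CurvatureField, discrete_curvature
from .histograms import CurvatureHistogram, bin_curvatures, raw_mean, weighted_average
from .mesh_io import TriangleMesh, nearest_vertex
from .phantoms import (
    BILATERAL_ROI,
    FRACTURE_ROI,
    make_bilateral,
    make_fracture_pair,
)
from .roi import MirrorPlane, ROISelection, mirror_roi, select_roi
from .similarity import bray_curtis, znorm_euclidean

__all__ = [
    "ROIAnalysis",
    "analyze_roi",
    "FractureCase",
    "fracture_case",
    "BilateralCase",
    "bilateral_case",
]


@dataclass(frozen=True)
class ROIAnalysis:
    """Curvature histogram and summary statistics of one region."""

    roi: ROISelection
    histogram: CurvatureHistogram
    weighted_average: float
    raw_mean: float
    n_undefined: int  # ROI vertices with no curvature (isolated)


def analyze_roi(
    mesh: TriangleMesh,
    center,
    radius: float,
    *,
    label: str = "roi",
    side: str = "affected",
    ring: int = 3,
    normal_rule: str = "area",
    field: CurvatureField | None = None,
    exclude_boundary: bool = False,
) -> ROIAnalysis:
    """Curvature statistics of the ball ROI around ``center``.

    A precomputed ``field`` (same mesh, same ring) avoids recomputing
    curvature when several ROIs are analyzed on one mesh. Vertices with
    undefined curvature are dropped; ``exclude_boundary`` additionally
    drops open-edge vertices.
    """
    if field is None:
        field = discrete_curvature(mesh, ring, normal_rule=normal_rule)
    roi = select_roi(mesh, center, radius, label, side)
    idx = roi.vertex_indices
    if exclude_boundary:
        idx = idx[~field.boundary[idx]]
    vals = field.defined_values(idx)
    if vals.size == 0:
        raise ValueError(f"ROI {label!r} contains no vertex with defined curvature")
    hist = bin_curvatures(vals)
    return ROIAnalysis(
        roi=roi,
        histogram=hist,
        weighted_average=weighted_average(hist),
        raw_mean=raw_mean(vals),
        n_undefined=int(roi.n_vertices - vals.size
                        - (0 if not exclude_boundary else int(field.boundary[roi.vertex_indices].sum()))),
    )


# ---------------------------------------------------------------------------
# Phantom studies
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FractureCase:
    """One synthetic 'patient': fracture step phantom, pre vs post reduction."""

    seed: int
    pre: ROIAnalysis
    post: ROIAnalysis

    @property
    def delta(self) -> float:
        return self.post.weighted_average - self.pre.weighted_average


def fracture_case(seed: int, *, ring: int = 3, radius: float | None = None,
                  **phantom_kwargs) -> FractureCase:
    """Run the fracture phantom through the pre/post curvature comparison.

    The ROI ball is centered on the step line at mid-depth (the vertex of
    the pre mesh nearest that point in x, y), the same center being used
    on the corresponding reduced mesh.
    """
    pre_mesh, post_mesh = make_fracture_pair(seed=seed, **phantom_kwargs)
    extent = phantom_kwargs.get("extent", 20.0)
    radius = FRACTURE_ROI["radius"] if radius is None else radius
    anchor = nearest_vertex(
        pre_mesh, (extent / 2.0, extent / 2.0, float(pre_mesh.vertices[:, 2].mean()))
    )
    center = pre_mesh.vertices[anchor]
    pre = analyze_roi(pre_mesh, center, radius, label="step", ring=ring)
    post_center = post_mesh.vertices[anchor]
    post = analyze_roi(post_mesh, post_center, radius, label="step", ring=ring)
    return FractureCase(seed=seed, pre=pre, post=post)


@dataclass(frozen=True)
class BilateralCase:
    """One synthetic 'patient': defect phantom, affected vs mirrored side,
    before (sharp, full-amplitude defect) and after (residual defect)."""

    seed: int
    bcsi_pre: float
    bcsi_post: float
    euclidean_z_pre: float
    euclidean_z_post: float
    histograms: dict  # labels: pre_affected, pre_unaffected, post_affected, post_unaffected


def bilateral_case(
    seed: int,
    *,
    ring: int = 3,
    amplitude_pre: float = 0.8,
    amplitude_post: float = 0.3,
    basis: str = "proportions",
    plane: MirrorPlane | None = None,
    **phantom_kwargs,
) -> BilateralCase:
    """Affected-vs-unaffected similarity before and after 'reduction'.

    Two bilateral phantoms share jitter (same seed): the pre-op one has
    the full defect amplitude, the post-op one a small residual. For each,
    the affected ROI on the defect is mirrored across the symmetry plane
    (x = 0 by construction, unless overridden), areas are equalized, and
    BCSI is computed; the z-normalized Euclidean distance uses the
    patient's four histograms as the z-score population.
    """
    if plane is None:
        plane = MirrorPlane((0.0, 0.0, 0.0), (1.0, 0.0, 0.0))
    defect_center = phantom_kwargs.get("defect_center", (7.5, 10.0))
    radius = phantom_kwargs.pop("roi_radius", BILATERAL_ROI["radius"])

    hists: dict[str, CurvatureHistogram] = {}
    for stage, amplitude in (("pre", amplitude_pre), ("post", amplitude_post)):
        mesh = make_bilateral(seed=seed, defect_amplitude=amplitude, **phantom_kwargs)
        field = discrete_curvature(mesh, ring)
        anchor = nearest_vertex(mesh, (*defect_center, float(mesh.vertices[:, 2].max())))
        center = mesh.vertices[anchor]
        affected = select_roi(mesh, center, radius, "defect", "affected")
        affected, mirrored = mirror_roi(mesh, affected, plane)
        for roi in (affected, mirrored):
            vals = field.defined_values(roi.vertex_indices)
            hists[f"{stage}_{roi.side}"] = bin_curvatures(vals)

    bc_pre = bray_curtis(hists["pre_affected"], hists["pre_unaffected"], basis)
    bc_post = bray_curtis(hists["post_affected"], hists["post_unaffected"], basis)
    return BilateralCase(
        seed=seed,
        bcsi_pre=bc_pre.bcsi,
        bcsi_post=bc_post.bcsi,
        euclidean_z_pre=znorm_euclidean(hists, "pre_affected", "pre_unaffected", basis),
        euclidean_z_post=znorm_euclidean(hists, "post_affected", "post_unaffected", basis),
        histograms=hists,
    )
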