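"""Synthetic surface phantoms with known geometry.

Patient CT surfaces are not public, so every stage of the pipeline is
exercised on generated meshes whose curvature is known analytically or
whose pre/post relationship is known by construction:

- ``make_plane``: flat grid, curvature identically 0;
- ``make_pyramid``: m-gonal pyramid whose apex curvature is exactly
  sin β for depression angle β (the pyramid is the defining picture of
  the curvature statistic: blunting the apex lowers C);
- ``make_icosphere``: subdivided icosahedron, curvature ≈ sin(φ/2) for
  neighbor angular spacing φ;
- ``make_fracture_pair``: a gently curved sheet with a sharp step
  (displaced fracture, step height defaults to the 2 mm displacement
  threshold used clinically) and its smoothly blended "reduced"
  counterpart, with vertex correspondence;
- ``make_bilateral``: a dome sheet exactly mirror-symmetric about x = 0
  except for a localized conical defect on the x > 0 side.

Phantom realism is deliberately minimal — sheets and solids with seeded
vertex jitter of at most 1% of the grid spacing — enough statistical
structure to drive every stage, with no attempt to mimic bone anatomy.
All generators are bit-reproducible given the same parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import trimesh

from .mesh_io import TriangleMesh

__all__ = [
    "PhantomSpec",
    "build_phantom",
    "make_plane",
    "make_pyramid",
    "make_icosphere",
    "make_fracture_pair",
    "make_bilateral",
    "FRACTURE_ROI",
    "BILATERAL_ROI",
]

#: default ROI (center is completed with the local surface height) and radius
#: for the fracture phantom's step region and the bilateral phantom's defect.
FRACTURE_ROI = {"radius": 3.0}
BILATERAL_ROI = {"radius": 4.0}

PHANTOM_KINDS = ("plane", "pyramid", "icosphere", "fracture_pair", "bilateral")


@dataclass(frozen=True)
class PhantomSpec:
    """A reproducible phantom recipe: kind, parameters, and jitter seed."""

    kind: str
    params: dict[str, Any] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in PHANTOM_KINDS:
            raise ValueError(f"kind must be one of {PHANTOM_KINDS}, got {self.kind!r}")


def build_phantom(spec: PhantomSpec):
    """Dispatch a PhantomSpec to its generator (used by the CLI)."""
    if spec.kind == "plane":
        return make_plane(**spec.params)
    if spec.kind == "pyramid":
        return make_pyramid(**spec.params)
    if spec.kind == "icosphere":
        return make_icosphere(**spec.params)
    if spec.kind == "fracture_pair":
        return make_fracture_pair(seed=spec.seed, **spec.params)
    return make_bilateral(seed=spec.seed, **spec.params)


def _grid_faces(nx: int, ny: int, mirror_split: int | None = None) -> np.ndarray:
    """Two triangles per cell of an nx × ny vertex grid (row-major).

    Cells left of column ``mirror_split`` use the opposite diagonal so the
    triangulation itself (not just the vertex positions) is the mirror
    image of the right half — required for exact bilateral symmetry.
    """
    i, j = np.meshgrid(np.arange(ny - 1), np.arange(nx - 1), indexing="ij")
    i, j = i.ravel(), j.ravel()
    v00 = i * nx + j
    v01 = v00 + 1
    v10 = v00 + nx
    v11 = v10 + 1
    left = np.zeros_like(j, dtype=bool) if mirror_split is None else j < mirror_split
    right = ~left
    faces = [
        np.stack([v00[right], v01[right], v11[right]], axis=1),
        np.stack([v00[right], v11[right], v10[right]], axis=1),
        np.stack([v00[left], v01[left], v10[left]], axis=1),
        np.stack([v01[left], v11[left], v10[left]], axis=1),
    ]
    return np.concatenate(faces).astype(np.int64)


def make_plane(n: int = 10, spacing: float = 1.0) -> TriangleMesh:
    """n × n flat grid at z = 0; (n−1)² × 2 faces, curvature 0 everywhere."""
    if n < 2:
        raise ValueError("grid size must be >= 2")
    xs = np.arange(n, dtype=float) * spacing
    X, Y = np.meshgrid(xs, xs, indexing="xy")
    vertices = np.stack([X.ravel(), Y.ravel(), np.zeros(n * n)], axis=1)
    return TriangleMesh(vertices, _grid_faces(n, n))


def make_pyramid(m: int = 6, beta_deg: float = 30.0) -> TriangleMesh:
    """m-gonal pyramid, apex at the origin, base vertices at unit distance.

    Each base vertex sits at depression angle ``beta_deg`` below the
    apex's tangent plane (the z = 0 plane, by symmetry), so the apex's
    ring-1 curvature is exactly sin β.
    """
    if m < 3:
        raise ValueError("need at least 3 base vertices")
    if not 0.0 < beta_deg < 90.0:
        raise ValueError("depression angle must be in (0, 90) degrees")
    beta = np.deg2rad(beta_deg)
    phi = 2.0 * np.pi * np.arange(m) / m
    base = np.stack(
        [np.cos(beta) * np.cos(phi), np.cos(beta) * np.sin(phi), -np.sin(beta) * np.ones(m)],
        axis=1,
    )
    vertices = np.vstack([[[0.0, 0.0, 0.0]], base])
    faces = np.stack(
        [np.zeros(m, dtype=np.int64), 1 + np.arange(m), 1 + (np.arange(m) + 1) % m],
        axis=1,
    )
    return TriangleMesh(vertices, faces)


def make_icosphere(subdiv: int = 2, radius: float = 1.0) -> TriangleMesh:
    """Icosahedron subdivided ``subdiv`` times, vertices projected to ``radius``."""
    if subdiv < 0:
        raise ValueError("subdivision level must be >= 0")
    ico = trimesh.creation.icosphere(subdivisions=subdiv, radius=radius)
    return TriangleMesh(np.asarray(ico.vertices, dtype=float), np.asarray(ico.faces))


def make_fracture_pair(
    grid_n: int = 41,
    extent: float = 20.0,
    step_height: float = 2.0,
    blend_width: float = 5.0,
    base_amplitude: float = 1.0,
    debris_amplitude: float | None = None,
    debris_band: float = 3.0,
    residual_fraction: float = 0.3,
    jitter: float = 0.01,
    seed: int = 0,
) -> tuple[TriangleMesh, TriangleMesh]:
    """Displaced-fracture sheet and its reduced counterpart.

    Both meshes share the same jittered (x, y) grid over [0, extent]² and
    a gentle sinusoidal base surface. The "pre" surface adds a sharp step
    of ``step_height`` at x = extent/2 (the displaced fragment; the
    default equals the 2 mm clinical displacement threshold) plus a
    jagged per-vertex "comminution" texture of amplitude
    ``debris_amplitude`` (default equal to the step height, so a zero step gives
    identical meshes) inside a band of half-width ``debris_band``
    around the fracture line — fracture edges are rough in both surface
    directions, which is what drives vertices into the high-curvature
    bins. The "post" surface replaces the step with a smooth logistic
    ramp of width ``blend_width`` and shrinks the texture to
    ``residual_fraction`` of its amplitude. Vertex correspondence is
    exact; ``step_height = 0`` with ``debris_amplitude = 0`` makes the
    two meshes identical.
    """
    if grid_n < 4:
        raise ValueError("grid too small")
    if step_height < 0:
        raise ValueError("step height must be >= 0")
    if step_height > extent:
        raise ValueError("step taller than the sheet extent")
    if debris_amplitude is None:
        debris_amplitude = step_height  # comminution scales with displacement
    spacing = extent / (grid_n - 1)
    xs = np.arange(grid_n, dtype=float) * spacing
    X, Y = np.meshgrid(xs, xs, indexing="xy")
    rng = np.random.default_rng(seed)
    jx = rng.uniform(-1.0, 1.0, X.shape) * jitter * spacing
    jy = rng.uniform(-1.0, 1.0, X.shape) * jitter * spacing
    jz = rng.uniform(-1.0, 1.0, X.shape) * jitter * spacing
    x = (X + jx).ravel()
    y = (Y + jy).ravel()
    base = base_amplitude * np.sin(np.pi * y / extent) + jz.ravel()

    x0 = extent / 2.0
    # triangular window over the fracture band, zero outside
    window = np.maximum(0.0, 1.0 - np.abs(x - x0) / debris_band)
    debris = rng.uniform(-1.0, 1.0, x.shape) * debris_amplitude * window
    pre_z = base + step_height * (x >= x0) + debris
    # logistic ramp: same asymptotes as the step, gentle knees
    post_z = (
        base
        + step_height / (1.0 + np.exp(-(x - x0) / (blend_width / 4.0)))
        + residual_fraction * debris
    )
    faces = _grid_faces(grid_n, grid_n)
    pre = TriangleMesh(np.stack([x, y, pre_z], axis=1), faces)
    post = TriangleMesh(np.stack([x, y, post_z], axis=1), faces)
    return pre, post


def make_bilateral(
    half_n: int = 31,
    ny: int = 41,
    half_extent: float = 15.0,
    depth: float = 20.0,
    dome_height: float = 2.0,
    defect_amplitude: float = 0.8,
    defect_center: tuple[float, float] = (7.5, 10.0),
    defect_radius: float = 2.0,
    texture_amplitude: float = 0.25,
    texture_waves: float = 4.0,
    jitter: float = 0.01,
    seed: int = 0,
) -> TriangleMesh:
    """Bilaterally symmetric dome sheet with a one-sided defect.

    The sheet spans x ∈ [−half_extent, half_extent], y ∈ [0, depth]. Its
    height is a smooth dome plus a corrugated "bone texture" (so both
    sides share a realistic curvature composition); jitter and texture
    are generated on the x ≥ 0 half and mirrored, so with
    ``defect_amplitude = 0`` the mesh is *exactly* symmetric about the
    x = 0 plane. A positive amplitude adds, on the x > 0 side only, a
    sharp displaced cone with jagged fragment noise scaled by the same
    amplitude — the fracture defect whose curvature the affected-side
    ROI picks up.
    """
    if defect_amplitude < 0:
        raise ValueError("defect amplitude must be >= 0")
    sx = half_extent / (half_n - 1)
    sy = depth / (ny - 1)
    xs_half = np.arange(half_n, dtype=float) * sx  # 0 .. half_extent
    ys = np.arange(ny, dtype=float) * sy
    Xh, Yh = np.meshgrid(xs_half, ys, indexing="xy")  # (ny, half_n)

    rng = np.random.default_rng(seed)
    jx = rng.uniform(-1.0, 1.0, Xh.shape) * jitter * sx
    jx[:, 0] = 0.0  # the x = 0 column stays on the mirror plane
    jy = rng.uniform(-1.0, 1.0, Xh.shape) * jitter * sy
    jz = rng.uniform(-1.0, 1.0, Xh.shape) * jitter * min(sx, sy)
    phase1, phase2 = rng.uniform(0.0, 2.0 * np.pi, 2)
    fragment_noise = rng.uniform(-1.0, 1.0, Xh.shape)  # defect jaggedness, half grid

    xh = Xh + jx
    yh = Yh + jy
    # mirrored corrugation: computed on the half grid, then reflected
    texture_h = (
        texture_amplitude
        * np.sin(2.0 * np.pi * texture_waves * Xh / half_extent + phase1)
        * np.sin(np.pi * texture_waves * Yh / depth + phase2)
    )
    # mirror the right half onto the left, sharing the x = 0 column
    x = np.concatenate([-xh[:, :0:-1], xh], axis=1)
    y = np.concatenate([yh[:, :0:-1], yh], axis=1)
    jz_full = np.concatenate([jz[:, :0:-1], jz], axis=1)
    texture = np.concatenate([texture_h[:, :0:-1], texture_h], axis=1)
    z = (
        dome_height
        * np.cos(np.pi * x / (2.0 * half_extent))
        * np.sin(np.pi * y / depth)
        + texture
        + jz_full
    )
    if defect_amplitude > 0:
        cx, cy = defect_center
        r = np.hypot(x - cx, y - cy)
        window = np.maximum(0.0, 1.0 - r / defect_radius)
        noise = np.concatenate(
            [np.zeros_like(fragment_noise[:, :0:-1]), fragment_noise], axis=1
        )
        z = z + defect_amplitude * window * (1.0 + 0.6 * noise)
    nx = 2 * half_n - 1
    vertices = np.stack([x.ravel(), y.ravel(), z.ravel()], axis=1)
    return TriangleMesh(vertices, _grid_faces(nx, ny, mirror_split=half_n - 1))
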