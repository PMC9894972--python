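"""Similarity between curvature histograms.

Three tools quantify how alike two regions' curvature compositions are:

- the Bray–Curtis similarity index, BC_ij = 2 C_ij / (S_i + S_j), where
  C_ij sums the per-bin lesser values and S_i, S_j are the histogram
  totals — 1 means identical composition, 0 disjoint;
- the z-score-normalized Euclidean distance: each of the ten bin
  variables is z-scored across a histogram *set* (sample standard
  deviation; zero-variance bins contribute 0), and the distance is the
  Euclidean norm of the difference of two z-vectors;
- agglomerative hierarchical clustering over those distances.

By default BC works on proportions (insensitive to residual vertex-count
imbalance between area-equalized regions); the raw-count basis of the
original formula is retained as an option.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .histograms import N_BINS, CurvatureHistogram

__all__ = [
    "SimilarityResult",
    "ClusterTree",
    "bray_curtis",
    "znorm_euclidean",
    "zscore_table",
    "hierarchical_cluster",
]

BASES = ("proportions", "counts")
LINKAGES = ("average", "complete", "single")


@dataclass(frozen=True)
class SimilarityResult:
    """Bray–Curtis decomposition for one histogram pair."""

    bcsi: float
    c_ij: float
    s_i: float
    s_j: float
    basis: str
    euclidean_z: float | None = None  # filled when a z-population is available


@dataclass(frozen=True)
class ClusterTree:
    """Agglomerative merge sequence over labeled histograms.

    ``merges`` lists (members_a, members_b, height) in merge order;
    heights are non-decreasing for the supported linkages.
    """

    leaves: tuple[str, ...]
    merges: tuple[tuple[frozenset, frozenset, float], ...]
    linkage: str

    def top_split(self) -> tuple[frozenset, frozenset]:
        """The two member sets joined by the final merge."""
        if not self.merges:
            return frozenset(self.leaves), frozenset()
        a, b, _ = self.merges[-1]
        return a, b

    def to_newick(self) -> str:
        """Nested-parenthesis rendering with merge heights."""
        node: dict[frozenset, str] = {frozenset([l]): l for l in self.leaves}
        for a, b, h in self.merges:
            node[a | b] = f"({node.pop(a)},{node.pop(b)}):{h:.6g}"
        if len(node) != 1:
            raise ValueError("merge sequence does not join all leaves")
        return next(iter(node.values())) + ";"


def _vector(h: CurvatureHistogram, basis: str) -> np.ndarray:
    if basis == "counts":
        return h.counts.astype(float)
    if basis == "proportions":
        return h.proportions
    raise ValueError(f"basis must be one of {BASES}, got {basis!r}")


def bray_curtis(
    h_i: CurvatureHistogram,
    h_j: CurvatureHistogram,
    basis: str = "proportions",
) -> SimilarityResult:
    """Bray–Curtis similarity BC = 2·Σmin / (S_i + S_j) of two histograms.

    With ``basis="proportions"`` the totals are both 1 and BC reduces to
    Σ min(p_i, p_j) = 1 − ½ Σ|p_i − p_j|.
    """
    for h in (h_i, h_j):
        if h.n_total == 0:
            raise ValueError("Bray-Curtis of an empty histogram is undefined")
    a, b = _vector(h_i, basis), _vector(h_j, basis)
    if a.shape != (N_BINS,) or b.shape != (N_BINS,):
        raise ValueError("histograms must share the 10-bin structure")
    c_ij = float(np.minimum(a, b).sum())
    s_i, s_j = float(a.sum()), float(b.sum())
    return SimilarityResult(
        bcsi=2.0 * c_ij / (s_i + s_j),
        c_ij=c_ij,
        s_i=s_i,
        s_j=s_j,
        basis=basis,
    )


def zscore_table(
    histograms: Mapping[str, CurvatureHistogram], basis: str = "proportions"
) -> tuple[list[str], np.ndarray]:
    """Z-score each bin variable across the histogram set.

    Uses the sample (n−1) standard deviation; a bin constant across the
    whole set maps to z = 0 everywhere. Returns (labels, (n, 10) z-matrix)
    in the mapping's iteration order.
    """
    labels = list(histograms)
    if len(labels) < 2:
        raise ValueError("z-scoring needs at least two histograms")
    mat = np.stack([_vector(histograms[l], basis) for l in labels])
    mu = mat.mean(axis=0)
    sd = mat.std(axis=0, ddof=1)
    z = np.zeros_like(mat)
    nz = sd > 0
    z[:, nz] = (mat[:, nz] - mu[nz]) / sd[nz]
    return labels, z


def znorm_euclidean(
    histograms: Mapping[str, CurvatureHistogram],
    a: str,
    b: str,
    basis: str = "proportions",
) -> float:
    """Euclidean distance between the z-vectors of histograms ``a`` and ``b``.

    The z-score population is exactly the set passed in (for the bilateral
    workflow: one patient's pre/post × affected/unaffected quartet).
    """
    for label in (a, b):
        if label not in histograms:
            raise KeyError(f"histogram {label!r} not in the supplied set")
    labels, z = zscore_table(histograms, basis)
    ia, ib = labels.index(a), labels.index(b)
    return float(np.linalg.norm(z[ia] - z[ib]))


def _cluster_key(members: frozenset) -> str:
    return min(members)


def hierarchical_cluster(
    histograms: Mapping[str, CurvatureHistogram],
    linkage: str = "average",
    basis: str = "proportions",
) -> ClusterTree:
    """Agglomerative clustering on z-normalized Euclidean distances.

    Linkage is average (default), complete, or single, updated with the
    Lance–Williams recurrences. Ties are broken deterministically by the
    lexicographically smallest (representative_a, representative_b) label
    pair, so the result is invariant to input order. A single histogram
    yields a degenerate one-leaf tree.
    """
    if linkage not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}, got {linkage!r}")
    labels = sorted(histograms)
    if len(labels) == 1:
        return ClusterTree(tuple(labels), (), linkage)
    _, z = zscore_table({l: histograms[l] for l in labels}, basis)
    n = len(labels)
    base = np.linalg.norm(z[:, None, :] - z[None, :, :], axis=2)

    clusters: dict[frozenset, int] = {frozenset([l]): i for i, l in enumerate(labels)}
    dist: dict[tuple[frozenset, frozenset], float] = {}
    sizes: dict[frozenset, int] = {c: 1 for c in clusters}
    cl = list(clusters)
    for i in range(n):
        for j in range(i + 1, n):
            dist[(cl[i], cl[j])] = float(base[i, j])

    def get(a: frozenset, b: frozenset) -> float:
        return dist[(a, b)] if (a, b) in dist else dist[(b, a)]

    merges = []
    active = set(clusters)
    while len(active) > 1:
        best = None
        for a in active:
            for b in active:
                if _cluster_key(a) >= _cluster_key(b):
                    continue
                key = (get(a, b), _cluster_key(a), _cluster_key(b))
                if best is None or key < best[0]:
                    best = (key, a, b)
        (h, _, _), a, b = best
        merged = a | b
        merges.append((a, b, h))
        active.discard(a)
        active.discard(b)
        for c in active:
            da, db = get(a, c), get(b, c)
            if linkage == "single":
                d = min(da, db)
            elif linkage == "complete":
                d = max(da, db)
            else:  # average
                na, nb = sizes[a], sizes[b]
                d = (na * da + nb * db) / (na + nb)
            dist[(merged, c)] = d
        sizes[merged] = sizes[a] + sizes[b]
        active.add(merged)
    return ClusterTree(tuple(labels), tuple(merges), linkage)
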