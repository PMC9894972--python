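"""Ten-bin curvature histograms and the weighted average of curvature.

Curvature lives in [0, 1]; the range is split into ten equal sections
with fixed midpoints 0.05, 0.15, …, 0.95. The headline per-region
statistic is the *weighted average of curvature*: each bin's midpoint
multiplied by the proportion of ROI vertices falling in that bin, then
summed. Bins are half-open [0.1k, 0.1(k+1)) with the last bin closed at
1.0 so every legal value has exactly one bin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "BIN_EDGES",
    "BIN_MIDPOINTS",
    "CurvatureHistogram",
    "HistogramDelta",
    "bin_curvatures",
    "weighted_average",
    "raw_mean",
    "histogram_delta",
]

N_BINS = 10
BIN_EDGES = np.linspace(0.0, 1.0, N_BINS + 1)
BIN_EDGES.setflags(write=False)
BIN_MIDPOINTS = (BIN_EDGES[:-1] + BIN_EDGES[1:]) / 2.0  # 0.05 ... 0.95
BIN_MIDPOINTS.setflags(write=False)


@dataclass(frozen=True)
class CurvatureHistogram:
    """Counts of curvature values over the ten fixed bins."""

    counts: np.ndarray  # (10,) non-negative int

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.shape != (N_BINS,):
            raise ValueError(f"counts must have shape ({N_BINS},), got {c.shape}")
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")
        c.setflags(write=False)
        object.__setattr__(self, "counts", c)

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())

    @property
    def proportions(self) -> np.ndarray:
        n = self.n_total
        if n == 0:
            return np.zeros(N_BINS)
        return self.counts / n

    @property
    def midpoints(self) -> np.ndarray:
        return BIN_MIDPOINTS

    @property
    def bin_edges(self) -> np.ndarray:
        return BIN_EDGES

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_low": BIN_EDGES[:-1],
                "bin_high": BIN_EDGES[1:],
                "count": self.counts,
                "proportion": self.proportions,
            }
        )


@dataclass(frozen=True)
class HistogramDelta:
    """Pre/post comparison of two histograms (post − pre)."""

    weighted_average_pre: float
    weighted_average_post: float
    delta: float
    proportion_shift: np.ndarray  # (10,) post − pre proportions
    pre: CurvatureHistogram
    post: CurvatureHistogram

    def to_frame(self) -> pd.DataFrame:
        """Two-series bar layout (pre vs post proportions per bin)."""
        return pd.DataFrame(
            {
                "bin_low": BIN_EDGES[:-1],
                "bin_high": BIN_EDGES[1:],
                "pre_proportion": self.pre.proportions,
                "post_proportion": self.post.proportions,
                "shift": self.proportion_shift,
            }
        )


def bin_curvatures(values) -> CurvatureHistogram:
    """Histogram curvature values into the ten fixed sections.

    v in [0.1k, 0.1(k+1)) goes to bin k; v = 1.0 to bin 9. Values outside
    [0, 1] raise — curvature is bounded by construction, so an
    out-of-range value signals an upstream bug, never data to clamp.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size and (np.any(np.isnan(v)) or v.min() < 0.0 or v.max() > 1.0):
        raise ValueError("curvature values must lie in [0, 1] and be defined")
    idx = np.minimum(np.floor(v * N_BINS).astype(np.int64), N_BINS - 1)
    return CurvatureHistogram(np.bincount(idx, minlength=N_BINS))


def weighted_average(hist: CurvatureHistogram) -> float:
    """Σ_k midpoint_k × proportion_k; in [0.05, 0.95] for nonempty input."""
    if hist.n_total == 0:
        raise ValueError("weighted average of an empty histogram is undefined")
    return float(BIN_MIDPOINTS @ hist.proportions)


def raw_mean(values) -> float:
    """Plain mean of the raw curvature values (secondary statistic)."""
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("mean of no values is undefined")
    return float(v.mean())


def histogram_delta(pre: CurvatureHistogram, post: CurvatureHistogram) -> HistogramDelta:
    """Paired pre/post summary: weighted averages, their difference, bin shifts."""
    wa_pre = weighted_average(pre)
    wa_post = weighted_average(post)
    return HistogramDelta(
        weighted_average_pre=wa_pre,
        weighted_average_post=wa_post,
        delta=wa_post - wa_pre,
        proportion_shift=post.proportions - pre.proportions,
        pre=pre,
        post=post,
    )
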