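"""Cohort statistics: paired t-test, Fleiss' kappa, and its interpretation.

The pre/post comparison of per-patient curvature statistics uses the
classic paired t-test (df = n−1, 95% CI). Intra-observer reliability of
repeated measurements uses Fleiss' kappa; because the measured quantity
(the weighted average of curvature) is continuous, each repeat is first
discretized into the ten standard curvature bins. The intraclass
correlation coefficient (one-way random effects, single measurement) is
emitted alongside as a clearly-labeled secondary statistic for users who
prefer a continuous-data agreement measure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats import inter_rater

from .histograms import N_BINS

__all__ = [
    "PairedSample",
    "PairedTResult",
    "paired_t_test",
    "fleiss_kappa",
    "interpret_kappa",
    "discretize_measurements",
    "intra_observer_reliability",
    "icc_oneway",
    "cohort_paired_tests",
    "KAPPA_SCALE",
]

#: (upper bound, label); a value belongs to the first band whose bound >= it.
KAPPA_SCALE = (
    (0.0, "poor"),          # < 0
    (0.20, "slight"),       # 0.01-0.20 (the [0, 0.01) gap maps here)
    (0.40, "fair"),         # 0.21-0.40
    (0.60, "moderate"),     # 0.41-0.60
    (0.80, "substantial"),  # 0.61-0.80
    (1.00, "almost perfect"),  # 0.81-1.00
)


@dataclass(frozen=True)
class PairedSample:
    """Per-patient pre and post values of one statistic."""

    labels: tuple[str, ...]
    pre: np.ndarray
    post: np.ndarray

    def __post_init__(self) -> None:
        pre = np.asarray(self.pre, dtype=float)
        post = np.asarray(self.post, dtype=float)
        if pre.shape != post.shape or pre.ndim != 1:
            raise ValueError("pre and post must be 1-D arrays of equal length")
        if len(self.labels) != pre.size:
            raise ValueError("labels must match the number of pairs")
        if pre.size < 2:
            raise ValueError("paired testing needs n >= 2")
        object.__setattr__(self, "pre", pre)
        object.__setattr__(self, "post", post)

    @property
    def n(self) -> int:
        return int(self.pre.size)


@dataclass(frozen=True)
class PairedTResult:
    t: float
    p: float
    df: int
    mean_difference: float  # mean(pre - post)
    ci_low: float
    ci_high: float


def paired_t_test(sample: PairedSample, confidence: float = 0.95) -> PairedTResult:
    """Classic paired t on the differences pre − post, df = n − 1.

    Identical pre and post (all differences zero) is the degenerate
    no-effect case and returns t = 0, p = 1; zero-variance differences
    with a nonzero mean leave t undefined and raise.
    """
    d = sample.pre - sample.post
    n = sample.n
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    df = n - 1
    if sd == 0.0:
        if mean == 0.0:
            return PairedTResult(0.0, 1.0, df, 0.0, 0.0, 0.0)
        raise ValueError("differences have zero variance; t is undefined")
    se = sd / np.sqrt(n)
    t = mean / se
    p = 2.0 * float(sps.t.sf(abs(t), df))
    tcrit = float(sps.t.ppf(0.5 + confidence / 2.0, df))
    return PairedTResult(
        t=float(t),
        p=p,
        df=df,
        mean_difference=mean,
        ci_low=mean - tcrit * se,
        ci_high=mean + tcrit * se,
    )


def fleiss_kappa(ratings: np.ndarray, n_categories: int | None = None) -> float:
    """Fleiss' kappa of a subjects × repeated-ratings table of category indices.

    kappa = (P̄ − P̄_e) / (1 − P̄_e) with P̄ the mean per-subject pairwise
    agreement and P̄_e = Σ_k p_k². Every subject must have the same number
    of ratings (≥ 2). If every rating across all subjects falls in one
    category, P̄_e = 1 and kappa is undefined (raises).
    """
    r = np.asarray(ratings, dtype=np.int64)
    if r.ndim != 2 or r.shape[1] < 2:
        raise ValueError("ratings must be subjects x raters with >= 2 raters")
    if r.min() < 0:
        raise ValueError("category indices must be non-negative")
    k = int(n_categories) if n_categories is not None else int(r.max()) + 1
    if r.max() >= k:
        raise ValueError("category index outside [0, n_categories)")
    table = np.stack([np.bincount(row, minlength=k) for row in r])
    p_cat = table.sum(axis=0) / table.sum()
    if np.max(p_cat) >= 1.0:
        raise ValueError(
            "all ratings fall in a single category; kappa is undefined (P_e = 1)"
        )
    return float(inter_rater.fleiss_kappa(table, method="fleiss"))


def interpret_kappa(k: float) -> str:
    """Map a kappa coefficient to the six-band reliability scale.

    Bands: < 0 poor; ≤ 0.20 slight; ≤ 0.40 fair; ≤ 0.60 moderate;
    ≤ 0.80 substantial; ≤ 1.00 almost perfect. Values above 1 are
    impossible for kappa and raise.
    """
    k = float(k)
    if np.isnan(k):
        raise ValueError("kappa is NaN")
    if k > 1.0:
        raise ValueError("kappa cannot exceed 1")
    if k < 0.0:
        return "poor"
    for bound, label in KAPPA_SCALE[1:]:
        if k <= bound:
            return label
    raise AssertionError("unreachable")


def discretize_measurements(values: np.ndarray) -> np.ndarray:
    """Assign each continuous curvature statistic in [0, 1] to its 10-bin index."""
    v = np.asarray(values, dtype=float)
    if np.any(np.isnan(v)) or v.min() < 0.0 or v.max() > 1.0:
        raise ValueError("measurements must lie in [0, 1]")
    return np.minimum(np.floor(v * N_BINS).astype(np.int64), N_BINS - 1)


def intra_observer_reliability(measurements: np.ndarray) -> dict:
    """Reliability of repeated continuous measurements (subjects × repeats).

    Repeats are discretized into the ten curvature bins, Fleiss' kappa is
    computed on the resulting categories, and the one-way ICC is added as
    a secondary continuous-data statistic.
    """
    m = np.asarray(measurements, dtype=float)
    cats = discretize_measurements(m)
    kappa = fleiss_kappa(cats, n_categories=N_BINS)
    return {
        "fleiss_kappa": kappa,
        "interpretation": interpret_kappa(kappa),
        "icc": icc_oneway(m),
        "discretization": "10 equal curvature bins on [0, 1]",
    }


def icc_oneway(measurements: np.ndarray) -> float:
    """ICC(1,1): one-way random effects, single measurement."""
    m = np.asarray(measurements, dtype=float)
    n, k = m.shape
    if n < 2 or k < 2:
        raise ValueError("ICC needs >= 2 subjects and >= 2 repeats")
    grand = m.mean()
    row_means = m.mean(axis=1)
    msb = k * ((row_means - grand) ** 2).sum() / (n - 1)
    msw = ((m - row_means[:, None]) ** 2).sum() / (n * (k - 1))
    denom = msb + (k - 1) * msw
    if denom == 0:
        raise ValueError("no variance at all; ICC is undefined")
    return float((msb - msw) / denom)


def cohort_paired_tests(
    cohort: pd.DataFrame,
    metrics: tuple[str, ...] = ("weighted_average", "bcsi", "euclidean_z"),
) -> pd.DataFrame:
    """Paired pre/post tests per region and metric over a cohort table.

    ``cohort`` columns: patient_id, region, stage ("pre"/"post") and one
    column per metric. Returns one row per (region, metric) with t, df, p,
    mean difference and 95% CI, pairing patients present at both stages.
    """
    required = {"patient_id", "region", "stage"}
    if not required.issubset(cohort.columns):
        raise ValueError(f"cohort table needs columns {sorted(required)}")
    present = [m for m in metrics if m in cohort.columns]
    rows = []
    for region, grp in cohort.groupby("region", sort=True):
        wide = grp.pivot_table(
            index="patient_id", columns="stage", values=present, aggfunc="mean"
        )
        for metric in present:
            try:
                sub = wide[metric][["pre", "post"]].dropna()
            except KeyError:
                continue
            if len(sub) < 2:
                continue
            sample = PairedSample(
                tuple(str(i) for i in sub.index),
                sub["pre"].to_numpy(),
                sub["post"].to_numpy(),
            )
            res = paired_t_test(sample)
            rows.append(
                {
                    "region": region,
                    "metric": metric,
                    "n": sample.n,
                    "pre_mean": float(sub["pre"].mean()),
                    "pre_sd": float(sub["pre"].std(ddof=1)),
                    "post_mean": float(sub["post"].mean()),
                    "post_sd": float(sub["post"].std(ddof=1)),
                    "t": res.t,
                    "df": res.df,
                    "p": res.p,
                    "mean_difference": res.mean_difference,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                }
            )
    return pd.DataFrame(rows)
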