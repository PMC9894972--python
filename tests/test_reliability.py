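"""Paired t-test, Fleiss' kappa, the interpretation scale, cohort tables."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from meshcurve import (
    PairedSample,
    cohort_paired_tests,
    fleiss_kappa,
    icc_oneway,
    interpret_kappa,
    intra_observer_reliability,
    paired_t_test,
)


def sample(pre, post):
    return PairedSample(tuple(f"p{i}" for i in range(len(pre))), pre, post)


class TestPairedT:
    def test_identical_pre_post_is_null(self):
        res = paired_t_test(sample([0.5, 0.6, 0.7], [0.5, 0.6, 0.7]))
        assert res.t == 0.0
        assert res.p == 1.0

    def test_hand_computed_example(self):
        # diffs (1, 1, 2): mean 4/3, sd 1/sqrt(3), t = 4.0 with df = 2
        res = paired_t_test(sample([1.0, 2.0, 3.0], [0.0, 1.0, 1.0]))
        assert res.t == pytest.approx(4.0, abs=1e-12)
        assert res.df == 2
        assert res.mean_difference == pytest.approx(4.0 / 3.0)

    def test_matches_scipy_ttest_rel(self):
        rng = np.random.default_rng(2)
        pre = rng.normal(0.5, 0.05, 15)
        post = pre - rng.normal(0.05, 0.03, 15)
        res = paired_t_test(sample(pre, post))
        ref = sps.ttest_rel(pre, post)
        assert res.t == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p == pytest.approx(ref.pvalue, abs=1e-12)
        lo, hi = ref.confidence_interval(0.95)
        assert res.ci_low == pytest.approx(lo, abs=1e-12)
        assert res.ci_high == pytest.approx(hi, abs=1e-12)

    def test_swap_flips_t_keeps_p(self):
        pre, post = [1.0, 2.0, 3.0], [0.0, 1.0, 1.0]
        a = paired_t_test(sample(pre, post))
        b = paired_t_test(sample(post, pre))
        assert b.t == pytest.approx(-a.t)
        assert b.p == pytest.approx(a.p)

    def test_zero_variance_nonzero_mean_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            paired_t_test(sample([1.0, 2.0, 3.0], [0.0, 1.0, 2.0]))

    def test_type_i_error_calibration(self):
        """Null rejection rate at alpha = 0.05 over 2000 replicates."""
        rng = np.random.default_rng(2026)
        rejections = 0
        reps, n = 2000, 12
        for _ in range(reps):
            pre = rng.normal(0.5, 0.1, n)
            post = rng.normal(0.5, 0.1, n)
            if paired_t_test(sample(pre, post)).p < 0.05:
                rejections += 1
        assert 0.035 < rejections / reps < 0.065


class TestFleissKappa:
    def test_perfect_agreement_is_one(self):
        ratings = np.array([[0, 0, 0], [1, 1, 1], [2, 2, 2], [1, 1, 1]])
        assert fleiss_kappa(ratings) == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # subjects (0,0,1) and (1,1,1): P = 2/3, Pe = 5/9, kappa = 0.25
        ratings = np.array([[0, 0, 1], [1, 1, 1]])
        assert fleiss_kappa(ratings) == pytest.approx(0.25, abs=1e-12)

    def test_random_ratings_near_zero(self):
        rng = np.random.default_rng(7)
        ratings = rng.integers(0, 4, size=(1000, 3))
        assert abs(fleiss_kappa(ratings)) < 0.05

    def test_category_relabeling_and_subject_order_invariance(self):
        rng = np.random.default_rng(3)
        ratings = rng.integers(0, 3, size=(40, 3))
        k0 = fleiss_kappa(ratings)
        relabel = np.array([2, 0, 1])[ratings]
        assert fleiss_kappa(relabel) == pytest.approx(k0, abs=1e-12)
        assert fleiss_kappa(ratings[::-1]) == pytest.approx(k0, abs=1e-12)

    def test_single_category_everywhere_undefined(self):
        with pytest.raises(ValueError, match="single category"):
            fleiss_kappa(np.zeros((5, 3), dtype=int))


class TestInterpretKappa:
    @pytest.mark.parametrize(
        "k,label",
        [
            (0.9, "almost perfect"),
            (0.5, "moderate"),
            (-0.1, "poor"),
            (0.20, "slight"),
            (0.21, "fair"),
            (0.40, "fair"),
            (0.41, "moderate"),
            (0.60, "moderate"),
            (0.61, "substantial"),
            (0.80, "substantial"),
            (0.81, "almost perfect"),
            (1.0, "almost perfect"),
            (0.005, "slight"),  # the printed scale's [0, 0.01) gap
            (-5.0, "poor"),
        ],
    )
    def test_scale_bands(self, k, label):
        assert interpret_kappa(k) == label

    def test_monotone_total_step_function(self):
        grid = np.linspace(-1.0, 1.0, 401)
        order = ["poor", "slight", "fair", "moderate", "substantial", "almost perfect"]
        ranks = [order.index(interpret_kappa(k)) for k in grid]
        assert all(b >= a for a, b in zip(ranks, ranks[1:]))

    def test_above_one_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            interpret_kappa(1.2)


class TestReliabilityWorkflow:
    def test_tight_repeats_are_almost_perfect(self):
        rng = np.random.default_rng(5)
        subjects = rng.uniform(0.1, 0.9, 12)
        repeats = subjects[:, None] + rng.normal(0, 0.004, (12, 3))
        out = intra_observer_reliability(np.clip(repeats, 0, 1))
        assert out["fleiss_kappa"] > 0.8
        assert out["interpretation"] == "almost perfect"
        assert out["icc"] > 0.95

    def test_icc_matches_anova_decomposition(self):
        rng = np.random.default_rng(8)
        m = rng.uniform(0, 1, (10, 3))
        n, k = m.shape
        groups = [m[i] for i in range(n)]
        msb = sps.f_oneway(*groups)  # sanity via scipy's between/within split
        grand = m.mean()
        ss_between = k * ((m.mean(axis=1) - grand) ** 2).sum()
        ss_within = ((m - m.mean(axis=1, keepdims=True)) ** 2).sum()
        msb_v = ss_between / (n - 1)
        msw_v = ss_within / (n * (k - 1))
        expected = (msb_v - msw_v) / (msb_v + (k - 1) * msw_v)
        assert icc_oneway(m) == pytest.approx(expected, abs=1e-12)
        # f_oneway's statistic is MSB/MSW for the same grouping
        assert msb.statistic == pytest.approx(msb_v / msw_v, abs=1e-9)


class TestCohortTable:
    def _cohort(self):
        rng = np.random.default_rng(11)
        rows = []
        for pid in range(8):
            for region in ("orbital_rim", "maxilla"):
                pre = rng.uniform(0.5, 0.6)
                rows.append(
                    dict(patient_id=pid, region=region, stage="pre",
                         weighted_average=pre, bcsi=rng.uniform(0.75, 0.85),
                         euclidean_z=rng.uniform(3, 5))
                )
                rows.append(
                    dict(patient_id=pid, region=region, stage="post",
                         weighted_average=pre - rng.uniform(0.05, 0.15),
                         bcsi=rng.uniform(0.85, 0.95),
                         euclidean_z=rng.uniform(1, 2))
                )
        return pd.DataFrame(rows)

    def test_one_row_per_region_metric(self):
        table = cohort_paired_tests(self._cohort())
        assert len(table) == 6  # 2 regions x 3 metrics
        assert set(table["region"]) == {"orbital_rim", "maxilla"}

    def test_directions_recovered(self):
        table = cohort_paired_tests(self._cohort()).set_index(["region", "metric"])
        for region in ("orbital_rim", "maxilla"):
            assert table.loc[(region, "weighted_average"), "mean_difference"] > 0
            assert table.loc[(region, "bcsi"), "mean_difference"] < 0
            assert table.loc[(region, "euclidean_z"), "mean_difference"] > 0
            assert (table.loc[region]["p"] < 0.05).all()

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="columns"):
            cohort_paired_tests(pd.DataFrame({"patient_id": [1]}))
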