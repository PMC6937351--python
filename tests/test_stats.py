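"""Mann-Whitney U, box summaries, intrapatient variability, trajectories."""

import warnings
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import qspect as q
from qspect.errors import ArgumentError, DataError
from qspect.simulate import LongitudinalSeries, TissueSample
from qspect.stats import mann_whitney


def brute_force_mw(x, y):
    """Independent oracle: U from pairwise comparisons, exact two-tailed p by
    enumerating every labeling of the pooled data."""
    x, y = list(x), list(y)
    n1, n2 = len(x), len(y)

    def u_of(a, b):
        return sum((ai > bj) + 0.5 * (ai == bj) for ai in a for bj in b)

    u_obs = u_of(x, y)
    pooled = x + y
    center = n1 * n2 / 2.0
    hits = total = 0
    for pick in combinations(range(n1 + n2), n1):
        a = [pooled[i] for i in pick]
        b = [pooled[i] for i in range(n1 + n2) if i not in pick]
        total += 1
        if abs(u_of(a, b) - center) >= abs(u_obs - center) - 1e-9:
            hits += 1
    return u_obs, hits / total


class TestMannWhitney:
    def test_fully_separated_small_samples(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.u_statistic == 0.0
        assert res.p_value == pytest.approx(0.1)
        assert res.method == "exact"

    def test_identical_multisets_give_p_one(self):
        res = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == 1.0

    def test_exact_matches_brute_force_with_and_without_ties(self):
        rng = np.random.default_rng(5)
        for n1 in range(1, 6):
            for n2 in range(1, 6):
                x = rng.integers(0, 4, n1).astype(float)  # heavy ties
                y = rng.integers(0, 4, n2).astype(float)
                u_ref, p_ref = brute_force_mw(x, y)
                res = mann_whitney(x, y, mode="exact")
                assert res.u_statistic == pytest.approx(u_ref)
                assert res.p_value == pytest.approx(p_ref)

    def test_exact_matches_scipy_without_ties(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            x = rng.normal(size=rng.integers(2, 7))
            y = rng.normal(size=rng.integers(2, 7))
            res = mann_whitney(x, y, mode="exact")
            ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_normal_approximation_matches_scipy(self):
        rng = np.random.default_rng(23)
        x = rng.normal(size=40)
        y = np.round(rng.normal(0.2, 1.0, size=60), 1)  # some ties
        res = mann_whitney(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided",
                               method="asymptotic", use_continuity=True)
        assert res.method == "normal-approximation"
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    @given(st.lists(st.integers(0, 9), min_size=1, max_size=8),
           st.lists(st.integers(0, 9), min_size=1, max_size=8))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_u_statistics_of_both_samples_sum_to_n1n2(self, x, y):
        u1 = mann_whitney(x, y).u_statistic
        u2 = mann_whitney(y, x).u_statistic
        assert u1 + u2 == pytest.approx(len(x) * len(y))

    @given(st.lists(st.floats(0.1, 50, allow_nan=False), min_size=2, max_size=6),
           st.lists(st.floats(0.1, 50, allow_nan=False), min_size=2, max_size=6))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_invariant_under_strictly_monotone_transform(self, x, y):
        base = mann_whitney(x, y)
        logd = mann_whitney(np.log(x), np.log(y))
        assert base.u_statistic == pytest.approx(logd.u_statistic)
        assert base.p_value == pytest.approx(logd.p_value)

    def test_exact_test_type_one_error_is_conservative(self):
        """Permutation-exact test at n=4 vs 4 rejects at most 5% under the null."""
        rng = np.random.default_rng(99)
        rejections = sum(
            mann_whitney(rng.uniform(size=4), rng.uniform(size=4)).p_value < 0.05
            for _ in range(1000))
        assert rejections / 1000 <= 0.05

    def test_empty_sample_rejected(self):
        with pytest.raises(ArgumentError):
            mann_whitney([], [1.0])


class TestCompareScanners:
    @staticmethod
    def _samples(rng, scanner, shift=0.0):
        return [TissueSample(t, scanner, np.abs(rng.normal(2.0 + shift, 0.5, 20)))
                for t in ("liver", "bladder", "heart_lv")]

    def test_cohort_compared_with_itself_is_all_ones(self):
        rng = np.random.default_rng(3)
        a = self._samples(rng, "infinia_me")
        b = [TissueSample(s.tissue, "symbia_lehr", s.suvs.copy()) for s in a]
        res = q.compare_scanners(a, b)
        assert np.all(res.table["p_value"] == 1.0)
        assert res.average_p == 1.0

    def test_disjoint_supports_at_parotid_sample_sizes(self):
        rng = np.random.default_rng(4)
        a = [TissueSample("r_parotid", "infinia_me", rng.uniform(1, 2, 16))]
        b = [TissueSample("r_parotid", "symbia_lehr", rng.uniform(10, 11, 14))]
        res = q.compare_scanners(a, b)
        assert res.table["p_value"].iloc[0] < 0.001

    def test_label_mismatch_rejected(self):
        a = [TissueSample("liver", "a", [1.0, 2.0])]
        b = [TissueSample("spleen", "b", [1.0, 2.0])]
        with pytest.raises(DataError):
            q.compare_scanners(a, b)

    def test_average_p_is_the_mean_of_the_table(self):
        rng = np.random.default_rng(8)
        res = q.compare_scanners(self._samples(rng, "a"),
                                 self._samples(rng, "b"))
        assert res.average_p == pytest.approx(res.table["p_value"].mean())


class TestIqrSummary:
    def test_hand_computed_quartiles(self):
        s = q.iqr_summary([1, 2, 3, 4, 5])
        assert (s.median, s.q1, s.q3, s.iqr) == (3.0, 2.0, 4.0, 2.0)
        assert s.outliers == ()

    def test_constant_sample(self):
        s = q.iqr_summary([2.2] * 10)
        assert s.iqr == 0.0 and s.outliers == ()

    def test_extreme_point_is_flagged(self):
        s = q.iqr_summary([1, 2, 3, 4, 100])
        assert s.outliers == (100.0,)
        assert s.whisker_high == 4.0


class TestIntrapatientVariability:
    def test_published_min_max_ratio(self):
        res = q.intrapatient_variability({"a": [0.5, 0.7], "b": [3.2, 3.0]})
        assert res.min_max_percent == pytest.approx(100 * 0.5 / 3.2)
        assert res.reported_percent == 16

    def test_identical_livers(self):
        res = q.intrapatient_variability({"a": [1.6, 1.6], "b": [1.6, 1.6]})
        assert res.min_max_percent == 100.0
        assert res.variance_of_mean == 0.0
        assert res.cohort_mean == pytest.approx(1.6)

    def test_single_study_patients_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="fewer than 2"):
            res = q.intrapatient_variability({"a": [1.0], "b": [2.0, 3.0]})
        assert res.n_patients == 1

    def test_synthetic_cohort_recovers_liver_mean(self):
        cohort = q.simulate_patient_cohort(q.CohortSpec(), seed=6)
        liver = {p: grp["mean_suv"].tolist()
                 for p, grp in cohort.liver_studies.groupby("patient_id")}
        res = q.intrapatient_variability(liver)
        assert abs(res.cohort_mean - 1.6) < 0.15
        assert res.n_patients == 28


class TestLongitudinal:
    @staticmethod
    def _series(values, weeks=None, scanners=None, liver=None):
        n = len(values)
        return LongitudinalSeries(
            "s", weeks if weeks is not None else np.arange(n, dtype=float),
            np.asarray(values, dtype=float),
            np.asarray(liver if liver is not None else [2.1] * n),
            tuple(scanners if scanners is not None else ["infinia_me"] * n))

    def test_published_reduction(self):
        series = self._series([12.0, 9.0, 6.0, 3.1])
        assert q.percent_reduction(series) == pytest.approx(100 * (1 - 3.1 / 12.0))
        assert q.report_percent(q.percent_reduction(series)) == 74

    def test_no_change_and_complete_response(self):
        assert q.percent_reduction(self._series([5.0, 5.0])) == 0.0
        assert q.percent_reduction(self._series([5.0, 0.0])) == 100.0

    def test_zero_baseline_rejected(self):
        with pytest.raises(ArgumentError):
            q.percent_reduction(self._series([0.0, 1.0]))

    def test_constant_liver_segment_summary(self):
        series = self._series([4.0, 3.0, 2.0, 1.0],
                              scanners=["infinia_me"] * 2 + ["symbia_lehr"] * 2,
                              liver=[2.1, 2.1, 1.9, 1.9])
        rep = q.trajectory_report(series)
        assert rep.liver_segments["infinia_me"] == (pytest.approx(2.1), 0.0)
        assert rep.liver_segments["symbia_lehr"] == (pytest.approx(1.9), 0.0)

    def test_monotone_series_gives_monotone_cumulative_change(self):
        rep = q.trajectory_report(self._series([10.0, 8.0, 5.0, 2.0]))
        change = rep.table["pct_change_from_baseline"].to_numpy()
        assert np.all(np.diff(change) < 0)

    def test_flare_series_percent_change(self):
        rep = q.trajectory_report(self._series([3.8, 17.1, 23.9]))
        change = rep.table["pct_change_from_baseline"].round(0).tolist()
        assert change == [0.0, 350.0, 529.0]

    def test_decreasing_weeks_rejected(self):
        with pytest.raises(ArgumentError):
            self._series([1.0, 2.0], weeks=np.array([2.0, 1.0]))
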