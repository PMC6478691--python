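"""Statistics: exact Mann-Whitney U, distance regression, group comparison."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sp_stats

from pulmolymph.stats_report import (
    compare_groups,
    correlate_with_distance,
    mann_whitney_u,
)


def brute_force_p(x, y, alternative="two-sided"):
    """Exhaustive enumeration over all rank assignments (tie-free data)."""
    n1, n2 = len(x), len(y)
    combined = sorted(x + y)
    obs_u = sum(1 for a in x for b in y if a > b)
    us = []
    for idx in itertools.combinations(range(n1 + n2), n1):
        xs = [combined[i] for i in idx]
        ys = [combined[i] for i in range(n1 + n2) if i not in idx]
        us.append(sum(1 for a in xs for b in ys if a > b))
    us = np.array(us)
    le = (us <= obs_u).mean()
    ge = (us >= obs_u).mean()
    if alternative == "two-sided":
        return min(1.0, 2 * min(le, ge))
    return ge if alternative == "greater" else le


class TestMannWhitney:
    def test_fully_separated_small_samples(self):
        U, p, method = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert U == 0
        assert p == pytest.approx(0.1)
        assert method == "exact"

    def test_identical_groups_give_half_u_and_p_one(self):
        x = [1.0, 2.0, 3.0, 4.0]
        U, p, _ = mann_whitney_u(x, list(x))
        assert U == pytest.approx(len(x)**2 / 2)
        assert p == pytest.approx(1.0)

    def test_exact_p_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(0)
        for n1, n2 in [(2, 3), (3, 3), (4, 5), (5, 5), (6, 7), (7, 7)]:
            x = list(rng.permutation(np.arange(1.0, n1 + n2 + 1))[:n1])
            y = [v for v in np.arange(1.0, n1 + n2 + 1) if v not in x]
            _, p, method = mann_whitney_u(x, y)
            assert method == "exact"
            assert p == pytest.approx(brute_force_p(x, y), abs=1e-12)

    def test_exact_matches_scipy_reference(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            x = rng.standard_normal(8)
            y = rng.standard_normal(6) + 0.5
            U, p, _ = mann_whitney_u(list(x), list(y))
            ref = sp_stats.mannwhitneyu(x, y, alternative="two-sided",
                                        method="exact")
            assert U == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_normal_approximation_close_to_exact_at_n12(self):
        rng = np.random.default_rng(2)
        x = list(rng.standard_normal(12))
        y = list(rng.standard_normal(12) + 0.3)
        _, p_exact, m1 = mann_whitney_u(x, y, exact_limit=12)
        _, p_norm, m2 = mann_whitney_u(x, y, exact_limit=0)
        assert (m1, m2) == ("exact", "normal")
        assert abs(p_exact - p_norm) <= 0.02

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 50), min_size=1, max_size=10),
           st.lists(st.integers(0, 50), min_size=1, max_size=10))
    def test_u_statistics_sum_to_n1n2(self, x, y):
        U_xy, _, _ = mann_whitney_u(x, y)
        U_yx, _, _ = mann_whitney_u(y, x)
        assert U_xy + U_yx == pytest.approx(len(x) * len(y))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestDistanceRegression:
    def test_perfect_line_recovered(self):
        d = np.arange(10.0)
        reg = correlate_with_distance(list(zip(d, 2 * d + 1)))
        assert reg.r == pytest.approx(1.0)
        assert reg.slope == pytest.approx(2.0)
        assert reg.intercept == pytest.approx(1.0)

    def test_anti_correlation(self):
        d = np.arange(10.0)
        reg = correlate_with_distance(list(zip(d, -d)))
        assert reg.r == pytest.approx(-1.0)

    def test_p_value_equals_scipy_pearson(self):
        rng = np.random.default_rng(3)
        d = rng.uniform(0, 3000, 25)
        v = 0.04 - 1e-5 * d + rng.normal(0, 0.01, 25)
        reg = correlate_with_distance(list(zip(d, v)))
        r_ref, p_ref = sp_stats.pearsonr(d, v)
        assert reg.r == pytest.approx(r_ref)
        assert reg.p == pytest.approx(p_ref)

    def test_exclusions_counted_and_dropped(self):
        d = np.arange(10.0)
        recs = list(zip(d, 3 * d))
        excluded = [False] * 8 + [True, True]
        reg = correlate_with_distance(recs, excluded)
        assert reg.n == 8
        assert reg.n_excluded == 2

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            correlate_with_distance([(1.0, 5.0), (2.0, 5.0), (3.0, 5.0)])


class TestGroupComparison:
    def test_identical_cohorts_give_p_one(self):
        rows = [{"volume_fraction": v, "sa_per_tissue_volume": v,
                 "fractal_dimension": v, "branch_count": v,
                 "junction_count": v, "mean_tortuosity": v}
                for v in (0.01, 0.02, 0.03, 0.04)]
        comp = compare_groups(rows, [dict(r) for r in rows])
        for m, entry in comp.per_measure.items():
            assert entry["p"] == pytest.approx(1.0)

    def test_shifted_measure_detected_stable_measure_not(self):
        rng = np.random.default_rng(4)
        def cohort(vf_shift, n):
            return [{"volume_fraction": float(rng.normal(0.02 + vf_shift,
                                                         0.004)),
                     "sa_per_tissue_volume": float(rng.normal(0.01, 0.002)),
                     "fractal_dimension": float(rng.normal(2.0, 0.2)),
                     "branch_count": float(rng.poisson(20)),
                     "junction_count": float(rng.poisson(8)),
                     "mean_tortuosity": float(rng.normal(1.2, 0.05))}
                    for _ in range(n)]
        control = cohort(0.0, 25)
        diseased = cohort(0.03, 20)
        comp = compare_groups(control, diseased)
        assert comp.per_measure["volume_fraction"]["p"] < 0.01
        assert comp.per_measure["mean_tortuosity"]["p"] > 0.05

    def test_bonferroni_column_optional(self):
        rows = [{"volume_fraction": v, "sa_per_tissue_volume": v,
                 "fractal_dimension": v, "branch_count": v,
                 "junction_count": v, "mean_tortuosity": v}
                for v in (1.0, 2.0, 3.0)]
        other = [{k: v + 10 for k, v in r.items()} for r in rows]
        raw = compare_groups(rows, other)
        adj = compare_groups(rows, other, bonferroni=True)
        assert "p_bonferroni" not in raw.per_measure["volume_fraction"]
        m = adj.per_measure["volume_fraction"]
        assert m["p_bonferroni"] == pytest.approx(min(1.0, m["p"] * 6))
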