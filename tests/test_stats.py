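"""Rankings, correlation, regression diagnostics and pairwise comparisons,
each checked against an independent oracle."""

import itertools
import math
import random

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pfsskit.errors import (ComparisonError, CorrelationError,
                            DomainValueError, LeverageError, RankingError)
from pfsskit.stats import (bonferroni_threshold, correlate,
                           mann_whitney_compare, metric_averages,
                           overlap_top_k, pairwise_campaign, rank_groups,
                           regression_diagnostics)


class TestRankGroups:
    def test_descending_for_cumpfss(self):
        ranking = rank_groups({"A": 2.0, "B": 1.0}, "cumpfss")
        assert [e.group_name for e in ranking] == ["A", "B"]
        assert [e.rank for e in ranking] == [1, 2]

    def test_tied_scores_share_dense_rank_lexicographic(self):
        ranking = rank_groups({"B": 1.0, "A": 1.0, "C": 0.5}, "gpfss")
        assert [(e.rank, e.group_name) for e in ranking] == [(1, "A"), (1, "B"), (2, "C")]

    def test_rms_ranks_ascending(self):
        ranking = rank_groups({"A": 2.0, "B": 1.0}, "RMS-ALL")
        assert [e.group_name for e in ranking] == ["B", "A"]

    def test_unknown_key_rejected(self):
        with pytest.raises(RankingError):
            rank_groups({"A": 1.0}, "TM-SCORE")

    @given(st.permutations(list("ABCDEF")))
    def test_total_order_stable_under_input_permutation(self, order):
        scores = {"A": 3.0, "B": 2.0, "C": 2.0, "D": 1.0, "E": 0.5, "F": 0.1}
        ranking = rank_groups({g: scores[g] for g in order}, "gpfss")
        assert [e.group_name for e in ranking] == ["A", "B", "C", "D", "E", "F"]
        assert sorted(e.group_name for e in ranking) == sorted(scores)


class TestOverlapTopK:
    def test_identical_rankings(self):
        groups = [f"g{i}" for i in range(30)]
        assert overlap_top_k(groups, groups, 25) == (25, 100.0)

    def test_disjoint(self):
        assert overlap_top_k(["a", "b"], ["c", "d"], 2) == (0, 0.0)

    def test_partial_overlap_percentage(self):
        rank1 = [f"g{i}" for i in range(25)]
        rank2 = [f"g{i}" for i in range(17)] + [f"h{i}" for i in range(8)]
        assert overlap_top_k(rank1, rank2, 25) == (17, 68.0)

    def test_k_larger_than_ranking_rejected(self):
        with pytest.raises(RankingError):
            overlap_top_k(["a"], ["a"], 2)


class TestCorrelate:
    def test_collinear(self):
        x = [1.0, 2.0, 3.0, 4.0]
        r, p = correlate(x, [2 * v + 1 for v in x])
        assert r == pytest.approx(1.0)
        r, _ = correlate(x, [-v for v in x])
        assert r == pytest.approx(-1.0)

    def test_matches_direct_covariance_formula(self):
        x = [0.80, 0.85, 0.88, 0.91, 0.95]
        y = [55.0, 60.0, 71.0, 73.0, 84.0]
        mx, my = sum(x) / 5, sum(y) / 5
        sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
        sxx = sum((a - mx) ** 2 for a in x)
        syy = sum((b - my) ** 2 for b in y)
        expected = sxy / math.sqrt(sxx * syy)
        r, p = correlate(x, y)
        assert r == pytest.approx(expected, rel=1e-12)
        assert 0 < p < 1

    def test_zero_variance_rejected(self):
        with pytest.raises(CorrelationError):
            correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    @given(st.floats(0.1, 10), st.floats(-5, 5), st.floats(0.1, 10), st.floats(-5, 5))
    def test_invariant_under_positive_affine_transforms(self, a, b, c, d):
        x = [0.1, 0.5, 0.7, 1.1, 1.4]
        y = [2.0, 1.0, 2.5, 3.0, 2.8]
        r0, _ = correlate(x, y)
        r1, _ = correlate([a * v + b for v in x], [c * v + d for v in y])
        assert r1 == pytest.approx(r0, abs=1e-9)


class TestRegressionDiagnostics:
    def _oracle(self, x, y):
        """Brute-force OLS + leverage + studentized residuals."""
        x, y = np.asarray(x), np.asarray(y)
        n = len(x)
        xbar = x.mean()
        sxx = ((x - xbar) ** 2).sum()
        slope = ((x - xbar) * (y - y.mean())).sum() / sxx
        intercept = y.mean() - slope * xbar
        e = y - (intercept + slope * x)
        s = math.sqrt((e ** 2).sum() / (n - 2))
        h = 1 / n + (x - xbar) ** 2 / sxx
        t = e / (s * np.sqrt(1 - h))
        return slope, intercept, h, t

    def test_matches_formula_oracle(self):
        rng = random.Random(3)
        x = [rng.uniform(0.7, 1.0) for _ in range(12)]
        y = [80 * v + rng.gauss(0, 2) for v in x]
        slope, intercept, h, t = self._oracle(x, y)
        diag = regression_diagnostics([f"g{i}" for i in range(12)], x, y, "LDDT")
        assert diag.slope == pytest.approx(slope, rel=1e-10)
        assert diag.intercept == pytest.approx(intercept, rel=1e-10)
        for pt, hi, ti in zip(diag.points, h, t):
            assert pt.leverage == pytest.approx(hi, rel=1e-10)
            assert pt.std_residual == pytest.approx(ti, rel=1e-10)

    def test_leverages_sum_to_two_and_residuals_sum_to_zero(self):
        rng = random.Random(11)
        for _ in range(5):
            n = rng.randint(5, 40)
            x = [rng.uniform(0, 1) for _ in range(n)]
            y = [rng.uniform(0, 100) for _ in range(n)]
            diag = regression_diagnostics([str(i) for i in range(n)], x, y)
            assert sum(p.leverage for p in diag.points) == pytest.approx(2.0, abs=1e-10)
            residuals = [p.y - (diag.intercept + diag.slope * p.x) for p in diag.points]
            assert sum(residuals) == pytest.approx(0.0, abs=1e-10)

    def test_perfectly_linear_data_has_no_outliers(self):
        x = [float(i) for i in range(8)]
        y = [3 * v - 1 for v in x]
        # tiny symmetric perturbation so the residual SD is nonzero
        y = [v + (0.001 if i % 2 else -0.001) for i, v in enumerate(y)]
        diag = regression_diagnostics([str(i) for i in range(8)], x, y)
        assert not any(p.outlier for p in diag.points)

    def test_gross_outlier_flagged_at_three_sigma(self):
        # n=15: an internally studentized residual is bounded by sqrt(n-2),
        # so a sample must have n >= 12 for any point to exceed 3
        x = [float(i) for i in range(15)]
        rng = random.Random(5)
        y = [2 * v + 1 + rng.gauss(0, 0.05) for v in x]
        y[4] += 10.0  # one grossly discordant observation
        diag = regression_diagnostics([str(i) for i in range(15)], x, y)
        flagged = [p for p in diag.points if p.outlier]
        assert [p.group_name for p in flagged] == ["4"]
        assert abs(flagged[0].std_residual) > 3

    def test_degenerate_x_rejected(self):
        with pytest.raises(LeverageError):
            regression_diagnostics(list("abcd"), [1.0] * 4, [1.0, 2.0, 3.0, 4.0])


def exact_mann_whitney_p(a, b):
    """Exhaustive enumeration oracle: distribute the pooled observations over
    the two samples in every possible way and tabulate the U statistic."""
    pooled = list(a) + list(b)
    n_a = len(a)
    indices = range(len(pooled))

    def u_of(sample_a_idx):
        sample_a = [pooled[i] for i in sample_a_idx]
        sample_b = [pooled[i] for i in indices if i not in sample_a_idx]
        u = 0.0
        for va in sample_a:
            for vb in sample_b:
                u += 1.0 if va > vb else (0.5 if va == vb else 0.0)
        return u

    observed = u_of(tuple(range(n_a)))
    us = [u_of(c) for c in itertools.combinations(indices, n_a)]
    n_total = len(us)
    p_le = sum(u <= observed for u in us) / n_total
    p_ge = sum(u >= observed for u in us) / n_total
    return observed, min(1.0, 2 * min(p_le, p_ge))


class TestMannWhitney:
    def test_identical_samples_not_separated(self):
        c = mann_whitney_compare([1.0, 2.0, 3.0, 4.0], [1.5, 2.5, 3.5, 0.5])
        assert c.p_value > 0.5

    def test_complete_separation_small_samples(self):
        c = mann_whitney_compare([1.0, 2.0, 3.0], [10.0, 11.0, 12.0])
        assert c.u_statistic == 0.0
        assert c.p_value == pytest.approx(0.1)  # 2/C(6,3) enumerated orderings

    def test_symmetric_in_sample_order(self):
        a, b = [1.0, 5.0, 3.0], [2.0, 8.0, 9.0, 4.0]
        assert (mann_whitney_compare(a, b).p_value
                == pytest.approx(mann_whitney_compare(b, a).p_value))

    def test_empty_sample_rejected(self):
        with pytest.raises(ComparisonError):
            mann_whitney_compare([], [1.0])

    @pytest.mark.parametrize("n_a,n_b", [(1, 2), (2, 2), (3, 3), (2, 5),
                                         (4, 4), (3, 7), (5, 5)])
    def test_agrees_with_exhaustive_enumeration(self, n_a, n_b):
        rng = random.Random(n_a * 100 + n_b)
        for _ in range(3):
            values = rng.sample(range(1000), n_a + n_b)  # tie-free
            a = [float(v) for v in values[:n_a]]
            b = [float(v) for v in values[n_a:]]
            u, p = exact_mann_whitney_p(a, b)
            c = mann_whitney_compare(a, b)
            assert c.u_statistic == pytest.approx(u)
            assert c.p_value == pytest.approx(p, rel=1e-9)


class TestBonferroni:
    def test_printed_threshold_for_51_comparisons(self):
        assert f"{bonferroni_threshold(0.05, 51):.5f}" == "0.00098"

    def test_single_comparison_unchanged(self):
        assert bonferroni_threshold(0.05, 1) == 0.05

    def test_simple_division(self):
        assert bonferroni_threshold(0.05, 5) == pytest.approx(0.01)

    @pytest.mark.parametrize("alpha,m", [(0.0, 5), (1.5, 5), (0.05, 0)])
    def test_invalid_inputs_rejected(self, alpha, m):
        with pytest.raises(DomainValueError):
            bonferroni_threshold(alpha, m)


class TestPairwiseCampaign:
    def test_restricted_to_full_coverage_groups(self):
        per_domain = {
            "full1": {"D1": 0.9, "D2": 0.8, "D3": 0.85},
            "full2": {"D1": 0.7, "D2": 0.6, "D3": 0.65},
            "full3": {"D1": 0.95, "D2": 0.9, "D3": 0.92},
            "partial": {"D1": 0.99, "D2": 0.98},
        }
        comparisons = pairwise_campaign(per_domain, {"D1", "D2", "D3"})
        names = {frozenset((c.group_a, c.group_b)) for c in comparisons}
        assert len(comparisons) == 3  # C(3, 2); the partial group is excluded
        assert all("partial" not in pair for pair in names)
        # Bonferroni divisor = comparisons per group = 3 qualifying groups - 1
        assert all(c.alpha_corrected == pytest.approx(0.05 / 2) for c in comparisons)
        assert all(c.n_common == 3 for c in comparisons)

    def test_fewer_than_two_groups_yields_no_comparisons(self):
        assert pairwise_campaign({"g": {"D1": 0.9}}, {"D1"}) == []


class TestMetricAverages:
    def test_average_restricted_to_domain_set(self):
        from pfsskit.io import MetricRecord
        records = [MetricRecord("g", "D1", "LDDT", 0.8),
                   MetricRecord("g", "D2", "LDDT", 0.6),
                   MetricRecord("g", "D1", "GDT-TS", 70.0)]
        assert metric_averages(records, "LDDT") == {"g": pytest.approx(0.7)}
        assert metric_averages(records, "LDDT", {"D1"}) == {"g": pytest.approx(0.8)}
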