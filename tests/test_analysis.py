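"""Cross-tabulation, discordance, utilization, flows and rank statistics."""

import itertools
import math

import numpy as np
import pytest

from riskpipe.analysis import (
    REC_ORDER,
    ReassignmentTable,
    cell_reassignment_fraction,
    cross_tabulate,
    discordance_percentage,
    mean_screens_per_woman_year,
    pearson_r2,
    rank_group_compare,
    round_half_up,
    sankey_flows,
    summarize_prs_by_group,
    trend_test,
)
from riskpipe.policy import AssignmentRecord, ScreeningRecommendation as SR


def rec(a, b, final=None, pid="p"):
    return AssignmentRecord(pid, 1, a, b, final)


class TestCrossTab:
    def test_single_cell(self):
        records = [rec(SR.BIENNIAL, SR.BIENNIAL, pid=f"p{i}") for i in range(3)]
        t = cross_tabulate(records)
        assert t.counts.loc["BIENNIAL", "BIENNIAL"] == 3
        assert t.n_total == 3

    def test_matches_brute_force_pair_counting(self, rng):
        cats = [r for r in REC_ORDER]
        pairs = [
            (cats[rng.integers(5)], cats[rng.integers(5)]) for _ in range(500)
        ]
        records = [rec(a, b, pid=f"p{i}") for i, (a, b) in enumerate(pairs)]
        t = cross_tabulate(records)
        for a in cats:
            for b in cats:
                assert t.counts.loc[a.value, b.value] == sum(
                    1 for x, y in pairs if x is a and y is b
                )

    def test_marginals_conserve_input_size(self, rng):
        cats = [r for r in REC_ORDER]
        records = [
            rec(cats[rng.integers(5)], cats[rng.integers(5)], pid=f"p{i}")
            for i in range(200)
        ]
        t = cross_tabulate(records)
        assert t.row_marginal().sum() == 200 == t.col_marginal().sum()

    def test_empty_input(self):
        t = cross_tabulate([])
        assert t.n_total == 0

    def test_pv_rows_rejected(self):
        with pytest.raises(ValueError, match="PV"):
            cross_tabulate([rec(SR.PV_GUIDELINE, SR.PV_GUIDELINE)])


class TestDiscordance:
    def test_identity_table_is_concordant(self):
        t = ReassignmentTable.from_dict("all", {(SR.BIENNIAL, SR.BIENNIAL): 10})
        assert discordance_percentage(t) == 0.0

    def test_empty_table_errors(self):
        t = ReassignmentTable.from_dict("all", {})
        with pytest.raises(ValueError):
            discordance_percentage(t)

    def test_concordant_row_fraction(self):
        t = ReassignmentTable.from_dict("all", {(SR.BIENNIAL, SR.BIENNIAL): 7})
        assert cell_reassignment_fraction(t, SR.BIENNIAL, SR.BIENNIAL) == 100.0

    def test_empty_row_errors(self):
        t = ReassignmentTable.from_dict("all", {(SR.BIENNIAL, SR.BIENNIAL): 7})
        with pytest.raises(ValueError):
            cell_reassignment_fraction(t, SR.ANNUAL_RISK, SR.BIENNIAL)


class TestUtilization:
    def test_all_biennial(self):
        mean, per = mean_screens_per_woman_year([SR.BIENNIAL] * 4)
        assert mean == 0.5 and per == 2

    def test_mixed_toy_set(self):
        recs = [SR.NONE_OR_STOP, SR.NONE_OR_STOP, SR.ANNUAL_RISK, SR.ANNUAL_RISK]
        mean, _ = mean_screens_per_woman_year(recs)
        assert mean == 0.5

    def test_no_screening_reciprocal_is_none(self):
        mean, per = mean_screens_per_woman_year([SR.NONE_OR_STOP] * 3)
        assert mean == 0.0 and per is None

    def test_counts_mapping_input(self):
        mean, per = mean_screens_per_woman_year({SR.BIENNIAL: 2, SR.Q6MO_ALTERNATING: 2})
        assert mean == 1.25 and per == 1

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            mean_screens_per_woman_year([])

    def test_missing_frequency_errors(self):
        with pytest.raises(KeyError):
            mean_screens_per_woman_year([SR.PV_GUIDELINE])


class TestSankey:
    def test_single_flow(self):
        flows = sankey_flows([rec(SR.BIENNIAL, SR.ANNUAL_RISK)])
        assert flows == [
            {"source": "bcsc:BIENNIAL", "target": "combined:ANNUAL_RISK", "count": 1}
        ]

    def test_conservation_and_enumeration(self, rng):
        cats = [SR.NONE_OR_STOP, SR.BIENNIAL, SR.ANNUAL_RISK]
        records = [
            rec(cats[rng.integers(3)], cats[rng.integers(3)],
                final=cats[rng.integers(3)], pid=f"p{i}")
            for i in range(300)
        ]
        flows = sankey_flows(records)
        t = cross_tabulate(records)
        # one flow per nonzero cell in the first stage
        stage1 = [f for f in flows if f["source"].startswith("bcsc:")]
        nonzero = int((t.counts.to_numpy() > 0).sum())
        assert len(stage1) == nonzero
        # flows out of each source node equal the model-A marginal
        for cat in cats:
            out = sum(f["count"] for f in stage1 if f["source"] == f"bcsc:{cat.value}")
            assert out == t.row_marginal()[cat.value]
        # total conservation at both stages
        stage2 = [f for f in flows if f["source"].startswith("combined:")]
        assert sum(f["count"] for f in stage1) == 300 == sum(f["count"] for f in stage2)


def exact_rank_sum_p(x, y):
    """Two-sided exact Wilcoxon rank-sum p by full enumeration of splits."""
    pooled = sorted(x + y)
    n1 = len(x)
    m = n1 * (len(pooled) - n1)

    def u_stat(xs, ys):
        return sum(1 for a in xs for b in ys if a > b)

    u_obs = u_stat(x, y)
    k = min(u_obs, m - u_obs)
    total = ge = le = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        u = u_stat(xs, ys)
        total += 1
        le += u <= k
        ge += u >= m - k
    return min(1.0, (le + ge) / total)


class TestRankCompare:
    def test_exact_small_sample(self):
        _, _, p = rank_group_compare([1, 2, 3, 4], ["a", "a", "b", "b"])
        assert p == pytest.approx(1 / 3, rel=1e-12)

    def test_complete_separation_n5(self):
        values = list(range(1, 11))
        labels = ["a"] * 5 + ["b"] * 5
        name, _, p = rank_group_compare(values, labels)
        assert name == "wilcoxon_rank_sum"
        assert p == pytest.approx(2 / 252, rel=1e-12)

    @pytest.mark.parametrize("n1,n2,seed", [(3, 4, 0), (4, 4, 1), (3, 5, 2)])
    def test_exact_p_matches_full_enumeration(self, n1, n2, seed):
        rng = np.random.default_rng(seed)
        vals = rng.permutation(np.arange(1, n1 + n2 + 1) * 1.0)
        x, y = list(vals[:n1]), list(vals[n1:])
        _, _, p = rank_group_compare(x + y, ["a"] * n1 + ["b"] * n2)
        assert p == pytest.approx(exact_rank_sum_p(x, y), rel=1e-12)

    def test_three_identical_groups_near_one(self, rng):
        vals = list(rng.normal(size=100))
        values = vals * 3
        labels = ["a"] * 100 + ["b"] * 100 + ["c"] * 100
        name, _, p = rank_group_compare(values, labels)
        assert name == "kruskal_wallis"
        assert p > 0.99

    def test_single_group_errors(self):
        with pytest.raises(ValueError):
            rank_group_compare([1, 2, 3], ["a", "a", "a"])


class TestTrend:
    def test_increasing_singletons_exact_sixth(self):
        stat, p = trend_test([1, 2, 3], ["lo", "mid", "hi"], ["lo", "mid", "hi"])
        assert stat == 3.0
        assert p == pytest.approx(1 / 6, rel=1e-12)

    def test_reversed_trend_p_above_half(self):
        _, p = trend_test([3, 2, 1], ["lo", "mid", "hi"], ["lo", "mid", "hi"])
        assert p > 0.5

    def test_identical_values_half_under_continuity(self):
        values = [5.0] * 30
        labels = ["lo"] * 10 + ["mid"] * 10 + ["hi"] * 10
        _, p = trend_test(values, labels, ["lo", "mid", "hi"])
        assert p == 0.5

    def test_strong_trend_large_n_rejects(self, rng):
        values = np.concatenate(
            [rng.normal(loc=mu, size=200) for mu in (0.0, 0.3, 0.6)]
        )
        labels = ["lo"] * 200 + ["mid"] * 200 + ["hi"] * 200
        _, p = trend_test(values, labels, ["lo", "mid", "hi"])
        assert p < 1e-6

    def test_unordered_labels_error(self):
        with pytest.raises(ValueError):
            trend_test([1, 2, 3], ["a", "b", "c"], ["a", "b"])


class TestPearson:
    def test_perfect_correlation(self):
        r2, _ = pearson_r2([1, 2, 3, 4], [1, 2, 3, 4])
        assert r2 == pytest.approx(1.0)

    def test_hand_computed_triple(self):
        r2, _ = pearson_r2([1, 2, 3], [2, 1, 3])
        assert r2 == pytest.approx(0.25, rel=1e-12)

    def test_independent_large_sample_near_zero(self, rng):
        x, y = rng.normal(size=100_000), rng.normal(size=100_000)
        r2, _ = pearson_r2(x, y)
        assert r2 < 0.001

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            pearson_r2([1, 1, 1], [1, 2, 3])


class TestGroupSummary:
    def test_hand_computation(self):
        (s,) = summarize_prs_by_group([1, 2, 3], ["g"] * 3)
        assert (s.n, s.mean, s.median, s.sd) == (3, 2.0, 2.0, 1.0)
        assert s.q1 == 1.5 and s.q3 == 2.5

    def test_singleton_sd_is_none(self):
        (s,) = summarize_prs_by_group([1.5], ["g"])
        assert s.sd is None and s.n == 1

    def test_equal_groups_identical_summaries(self):
        vals = [0.5, 1.0, 2.0]
        out = summarize_prs_by_group(vals * 2, ["a"] * 3 + ["b"] * 3)
        a, b = out
        assert (a.mean, a.sd, a.median, a.q1, a.q3) == (b.mean, b.sd, b.median, b.q1, b.q3)

    def test_quartile_order_invariant(self, rng):
        vals = rng.lognormal(size=500)
        (s,) = summarize_prs_by_group(vals, ["g"] * 500)
        assert s.q1 <= s.median <= s.q3


class TestRounding:
    @pytest.mark.parametrize("x,expected", [(13.8, 14), (10.37, 10), (6.5, 7), (4.49, 4)])
    def test_half_up(self, x, expected):
        assert round_half_up(x) == expected
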