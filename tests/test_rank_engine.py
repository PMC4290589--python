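import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from draftrank import benchmark_data as bench
from draftrank.rank_engine import (
    Direction,
    Group,
    GroupWeights,
    MetricSpec,
    MetricTable,
    Ties,
    build_rank_table,
    group_rank,
    overall_rank,
    rank_values,
)


class TestRankValues:
    def test_published_time_row_with_tie(self):
        # two assemblers tied at 1.02 h share rank 2; the next gets rank 4
        times = [2.43, 7.65, 1.02, 0.89, 17.41, 1.24, 1.02]
        assert rank_values(times, Direction.LOWER_BETTER) == [
            5, 6, 2, 1, 7, 4, 2,
        ]

    @pytest.mark.parametrize("table, ranks", [
        (bench.RUNNING_TIME_H, bench.RUNNING_TIME_RANKS),
        (bench.PEAK_MEMORY_GB, bench.PEAK_MEMORY_RANKS),
    ], ids=["time", "memory"])
    def test_reproduces_all_published_benchmark_ranks(self, table, ranks):
        for dataset in table.index:
            got = rank_values(table.loc[dataset].tolist(), "lower_better")
            expected = ranks.loc[dataset].tolist()
            assert got == pytest.approx(expected, nan_ok=True), dataset

    def test_all_equal_get_rank_one(self):
        assert rank_values([3.0, 3.0, 3.0]) == [1.0, 1.0, 1.0]

    def test_competition_vs_dense(self):
        vals = [1.02, 1.02, 1.24]
        assert rank_values(vals, ties="competition") == [1.0, 1.0, 3.0]
        assert rank_values(vals, ties="dense") == [1.0, 1.0, 2.0]

    def test_higher_better_reverses(self):
        assert rank_values([10, 30, 20], "higher_better") == [3.0, 1.0, 2.0]

    def test_missing_values_leave_no_gap(self):
        got = rank_values([5.0, math.nan, 1.0, 3.0])
        assert got[0] == 3.0 and math.isnan(got[1])
        assert got[2] == 1.0 and got[3] == 2.0

    def test_all_missing_is_error(self):
        with pytest.raises(ValueError, match="all values missing"):
            rank_values([math.nan, None])

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.floats(0, 1e6, allow_nan=False), min_size=1,
                    max_size=30, unique=True))
    def test_no_ties_gives_permutation_of_1_to_k(self, values):
        got = rank_values(values)
        assert sorted(got) == list(map(float, range(1, len(values) + 1)))
        assert rank_values(values, ties="dense") == got

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.floats(0, 100, allow_nan=False), min_size=2,
                    max_size=20),
           st.randoms(use_true_random=False))
    def test_permutation_equivariance(self, values, rnd):
        perm = list(range(len(values)))
        rnd.shuffle(perm)
        base = rank_values(values)
        permuted = rank_values([values[i] for i in perm])
        assert permuted == [base[i] for i in perm]


class TestGroupAndOverallRank:
    def test_unweighted_mean(self):
        assert group_rank([1, 2, 3]) == pytest.approx(2.0)

    def test_conservation_weights_fix_equal_ranks(self):
        # weights sum to n=4, so equal ranks map to themselves
        w = [0.76, 0.92, 1.04, 1.28]
        assert group_rank([1, 1, 1, 1], w) == pytest.approx(1.0)
        assert group_rank([3, 3, 3, 3], w) == pytest.approx(3.0)

    def test_weighted_hand_example(self):
        got = group_rank([1, 2, 3, 4], [0.76, 0.92, 1.04, 1.28])
        assert got == pytest.approx((0.76 + 1.84 + 3.12 + 5.12) / 4)
        assert got == pytest.approx(2.71)

    def test_overall_rank_means(self):
        assert overall_rank([2.0, 1.0, 1.0]) == pytest.approx(4 / 3)
        assert overall_rank([1.5, 2.0, 2.5]) == pytest.approx(2.0)
        assert overall_rank([2.7, 2.7]) == pytest.approx(2.7)

    def test_length_mismatch_is_error(self):
        with pytest.raises(ValueError):
            group_rank([1, 2], [1.0])
        with pytest.raises(ValueError):
            overall_rank([1.0], [1.0, 2.0])


def _specs_two_groups():
    return (
        MetricSpec("m1", Group.G1, Direction.HIGHER_BETTER),
        MetricSpec("m2", Group.G1, Direction.LOWER_BETTER),
        MetricSpec("m3", Group.G2, Direction.LOWER_BETTER),
    )


def _table(values: dict, specs=None) -> MetricTable:
    frame = pd.DataFrame(values).T
    frame.columns = [s.metric_id for s in (specs or _specs_two_groups())]
    return MetricTable.from_frame(frame, list(specs or _specs_two_groups()))


class TestBuildRankTable:
    def test_best_on_all_metrics_gets_group_rank_one(self):
        table = _table({
            "A": [100, 1, 0.0],
            "B": [50, 2, 5.0],
            "C": [10, 3, 9.0],
        })
        rt = build_rank_table(table)
        assert rt.group_ranks.loc["A", "g1"] == pytest.approx(1.0)
        assert rt.overall["A"] == pytest.approx(1.0)
        assert rt.overall["C"] == pytest.approx(3.0)
        assert rt.incomplete == ()

    def test_single_item_all_ranks_one(self):
        rt = build_rank_table(_table({"only": [5, 5, 5]}))
        assert rt.overall["only"] == pytest.approx(1.0)

    def test_item_missing_all_values_unranked_without_gap(self):
        vals = [2.43, 7.65, 1.02, 0.89, math.nan, 1.24, 1.03]
        specs = (MetricSpec("t", Group.G1, Direction.LOWER_BETTER),)
        frame = pd.DataFrame({"t": vals},
                             index=list("ABCDEFG"))
        rt = build_rank_table(MetricTable.from_frame(frame, list(specs)))
        assert math.isnan(rt.metric_ranks.loc["E", "t"])
        assert sorted(rt.metric_ranks["t"].dropna()) == [1, 2, 3, 4, 5, 6]
        assert rt.incomplete == ("E",)
        assert math.isnan(rt.overall["E"])

    def test_computational_metrics_excluded_from_overall(self):
        specs = _specs_two_groups() + (
            MetricSpec("running_time", Group.COMPUTATIONAL,
                       Direction.LOWER_BETTER),
        )
        table = _table({
            "A": [100, 1, 0.0, 99.0],   # best quality, worst time
            "B": [50, 2, 5.0, 1.0],
        }, specs)
        rt = build_rank_table(table)
        # A is worst on time yet R stays 1: overall uses g1/g2 only
        assert rt.overall["A"] == pytest.approx(1.0)
        assert rt.metric_ranks.loc["A", "running_time"] == 2.0

    def test_reference_item_excluded_from_computational_ranking(self):
        specs = (
            MetricSpec("m1", Group.G1, Direction.HIGHER_BETTER),
            MetricSpec("running_time", Group.COMPUTATIONAL,
                       Direction.LOWER_BETTER),
        )
        frame = pd.DataFrame(
            {"m1": [10.0, 20.0, 30.0], "running_time": [1.0, 2.0, 0.5]},
            index=["A", "B", "df_1"],
        )
        rt = build_rank_table(
            MetricTable.from_frame(frame, list(specs)),
            exclude_from_computational=["df_1"],
        )
        assert math.isnan(rt.metric_ranks.loc["df_1", "running_time"])
        assert rt.metric_ranks.loc["A", "running_time"] == 1.0
        assert not math.isnan(rt.overall["df_1"])

    def test_dense_flag_changes_only_tied_ranks(self):
        specs = (MetricSpec("t", Group.G1, Direction.LOWER_BETTER),)
        frame = pd.DataFrame({"t": [1.02, 1.02, 1.24, 2.0]},
                             index=list("ABCD"))
        table = MetricTable.from_frame(frame, list(specs))
        comp = build_rank_table(table, ties="competition")
        dense = build_rank_table(table, ties="dense")
        assert comp.metric_ranks["t"].tolist() == [1, 1, 3, 4]
        assert dense.metric_ranks["t"].tolist() == [1, 1, 2, 3]

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.integers(0, 10_000))
    def test_improving_one_value_never_worsens_ranks(self, seed):
        rng = np.random.default_rng(seed)
        n_items = int(rng.integers(2, 8))
        items = [f"i{j}" for j in range(n_items)]
        frame = pd.DataFrame(
            rng.uniform(0, 100, size=(n_items, 3)),
            index=items,
            columns=["m1", "m2", "m3"],
        )
        table = MetricTable.from_frame(frame, list(_specs_two_groups()))
        before = build_rank_table(table)
        target = items[int(rng.integers(0, n_items))]
        metric = ["m1", "m2", "m3"][int(rng.integers(0, 3))]
        spec = table.spec_for(metric)
        bump = float(rng.uniform(0, 50))
        frame2 = frame.copy()
        if spec.direction is Direction.HIGHER_BETTER:
            frame2.loc[target, metric] += bump
        else:
            frame2.loc[target, metric] -= bump
        after = build_rank_table(
            MetricTable.from_frame(frame2, list(_specs_two_groups()))
        )
        assert (after.metric_ranks.loc[target, metric]
                <= before.metric_ranks.loc[target, metric])
        assert after.overall[target] <= before.overall[target] + 1e-12

    def test_duplicate_items_rejected(self):
        frame = pd.DataFrame({"m1": [1.0, 2.0], "m2": [1, 2], "m3": [1, 2]},
                             index=["A", "A"])
        with pytest.raises(ValueError, match="unique"):
            MetricTable.from_frame(frame, list(_specs_two_groups()))

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(ValueError, match="weight"):
            MetricSpec("m", Group.G1, Direction.HIGHER_BETTER, 0.0)
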