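"""Possession summaries, transition-matrix estimation, passing channels."""

import itertools

import numpy as np
import pandas as pd
import pytest

from tacticalspace import (
    SimulationConfig,
    possession_summary,
    probable_channels,
    simulate_match,
    transition_matrix,
)
from tacticalspace.errors import InsufficientDataError

COLS = ["t_start_s", "t_end_s", "holder", "outcome", "receiver"]


def ev(rows):
    return pd.DataFrame(rows, columns=COLS)


class TestPossession:
    def test_single_possession_mean(self):
        per, pooled = possession_summary(ev([[0.0, 3.0, "A1", "turnover", ""]]))
        assert pooled == pytest.approx(3.0)
        assert per["A1"] == pytest.approx(3.0)

    def test_mean_of_two_durations(self):
        events = ev([[0, 2, "A1", "pass", "A2"], [2, 6, "A1", "turnover", ""]])
        _, pooled = possession_summary(events)
        assert pooled == pytest.approx(3.0)

    def test_truncated_trailing_possession_excluded(self):
        events = ev([[0, 2, "A1", "pass", "A2"], [2, 300, "A2", "out_of_time", ""]])
        per, pooled = possession_summary(events)
        assert pooled == pytest.approx(2.0)
        assert "A2" not in per.index

    def test_empty_log_rejected(self):
        with pytest.raises(InsufficientDataError):
            possession_summary(ev([]))

    def test_simulated_durations_recover_generator_mean(self):
        cfg = SimulationConfig(duration_s=900.0, seed=13, possession_mean_s=3.0)
        _, events, truth = simulate_match(cfg)
        _, pooled = possession_summary(events)
        n = (events["outcome"] != "out_of_time").sum()
        assert n > 200
        assert abs(pooled - truth.possession_mean_s) <= 3 * truth.possession_mean_s / np.sqrt(n)


class TestTransitionMatrix:
    def test_hand_counted_row(self):
        events = ev(
            [
                [0, 1, "A1", "pass", "A2"],
                [1, 2, "A2", "pass", "A1"],
                [2, 3, "A1", "pass", "A2"],
                [3, 4, "A2", "pass", "A1"],
                [4, 5, "A1", "pass", "A2"],
                [5, 6, "A2", "pass", "A1"],
                [6, 7, "A1", "turnover", ""],
            ]
        )
        net = transition_matrix(events)
        assert net.probabilities.loc["A1", "A2"] == pytest.approx(0.75)
        assert net.probabilities.loc["A1", "turnover"] == pytest.approx(0.25)

    def test_populated_rows_are_stochastic_and_counts_conserved(self):
        cfg = SimulationConfig(duration_s=300.0, seed=21)
        _, events, _ = simulate_match(cfg)
        net = transition_matrix(events)
        sums = net.probabilities.sum(axis=1)
        for h in net.players:
            if h not in net.zero_rows:
                assert sums[h] == pytest.approx(1.0, abs=1e-12)
        n_completed = (events["outcome"] != "out_of_time").sum()
        assert net.n_interactions == n_completed

    def test_diagonal_is_zero(self):
        cfg = SimulationConfig(duration_s=300.0, seed=22)
        _, events, _ = simulate_match(cfg)
        net = transition_matrix(events)
        for h in net.players:
            assert net.counts.loc[h, h] == 0

    def test_estimation_error_shrinks_with_sample_size(self):
        errs = []
        for duration in (1500.0, 15000.0):
            cfg = SimulationConfig(condition="free", duration_s=duration, seed=17)
            _, events, truth = simulate_match(cfg)
            net = transition_matrix(events, players=list(truth.transition.index))
            est = net.probabilities[truth.transition.columns].to_numpy()
            errs.append(np.max(np.abs(est - truth.transition.to_numpy())))
        assert errs[1] < errs[0]


class TestChannels:
    def _toy_network(self):
        events = ev(
            [
                [0, 1, "A", "pass", "B"],
                [1, 2, "B", "pass", "C"],
                [2, 3, "C", "goal", ""],
                [3, 4, "A", "pass", "C"],
                [4, 5, "C", "goal", ""],
                [5, 6, "B", "turnover", ""],
                [6, 7, "A", "pass", "B"],
                [7, 8, "B", "pass", "C"],
                [8, 9, "C", "pass", "A"],
                [9, 10, "A", "pass", "B"],
                [10, 11, "B", "goal", ""],
            ]
        )
        return transition_matrix(events, players=["A", "B", "C"])

    def test_deterministic_chain_probability_one(self):
        events = ev([[0, 1, "A", "pass", "B"], [1, 2, "B", "goal", ""]])
        net = transition_matrix(events, players=["A", "B"])
        channels = probable_channels(net, sources=["A"], sink="goal")
        assert channels[0][0] == ["A", "B", "goal"]
        assert channels[0][1] == pytest.approx(1.0)

    def test_higher_probability_branch_ranks_first(self):
        events = ev(
            [
                [0, 1, "A", "pass", "B"],
                [1, 2, "B", "goal", ""],
                [2, 3, "A", "pass", "B"],
                [3, 4, "B", "goal", ""],
                [4, 5, "A", "pass", "B"],
                [5, 6, "B", "goal", ""],
                [6, 7, "A", "pass", "C"],
                [7, 8, "C", "goal", ""],
                [8, 9, "A", "pass", "C"],
                [9, 10, "C", "goal", ""],
            ]
        )
        net = transition_matrix(events, players=["A", "B", "C"])
        channels = probable_channels(net, sources=["A"], sink="goal", k=2)
        assert channels[0][0][1] == "B"  # 0.6 branch before the 0.4 branch

    def test_ranking_matches_exhaustive_enumeration(self):
        net = self._toy_network()
        g = net.graph()
        # independent brute force: all loop-free node orderings A..sink
        best = []
        nodes = ["A", "B", "C"]
        for r in range(1, len(nodes) + 1):
            for mid in itertools.permutations(nodes, r):
                if mid[0] != "A":
                    continue
                path = list(mid) + ["goal"]
                prob = 1.0
                ok = True
                for u, v in zip(path[:-1], path[1:]):
                    if not g.has_edge(u, v):
                        ok = False
                        break
                    prob *= g[u][v]["probability"]
                if ok:
                    best.append((path, prob))
        best.sort(key=lambda pr: (-pr[1], pr[0]))
        channels = probable_channels(net, sources=["A"], sink="goal", k=len(best))
        assert [p for p, _ in channels] == [p for p, _ in best]
        assert np.allclose([v for _, v in channels], [v for _, v in best])

    def test_unreachable_sink_yields_empty(self):
        events = ev([[0, 1, "A", "pass", "B"], [1, 2, "B", "turnover", ""]])
        net = transition_matrix(events, players=["A", "B"])
        assert probable_channels(net, sources=["A"], sink="goal") == []
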