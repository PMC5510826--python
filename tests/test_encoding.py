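"""Configuration-state encoding: filtering, binning, tactical rules, 4-hot."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tacticalspace import (
    BinningScheme,
    FrameContext,
    TacticalThresholds,
    classify_tactical_action,
    encode_all,
    encode_player,
    movement_speed,
    second_windows,
    smooth_track,
)
from tacticalspace.encoding import distance_to_target, nearest_opponent_distance
from tacticalspace.errors import EncodingError, InsufficientDataError, UnknownPlayerError


class TestPreprocessing:
    def test_smoothing_averages_adjacent_frames(self):
        raw = np.array([[0.0, 0.0], [2.0, 0.0], [4.0, 2.0]])
        out = smooth_track(raw)
        assert np.allclose(out, [[0, 0], [1, 0], [3, 1]])

    def test_smoothing_keeps_constant_track(self):
        raw = np.tile([3.0, 4.0], (10, 1))
        assert np.allclose(smooth_track(raw), raw)

    def test_smoothing_preserves_length(self):
        raw = np.random.default_rng(0).normal(size=(1500, 2))
        assert smooth_track(raw).shape == (1500, 2)

    def test_smoothing_needs_two_frames(self):
        with pytest.raises(InsufficientDataError):
            smooth_track(np.array([[1.0, 2.0]]))

    def test_second_windows_collapse_5hz_to_1hz(self):
        xy = np.random.default_rng(1).normal(size=(1500, 2))
        assert second_windows(xy, 5.0).shape == (300, 2)

    def test_second_window_is_the_frame_mean(self):
        xy = np.array([[0.0, 0], [1, 0], [2, 0], [3, 0], [4, 0]])
        assert np.allclose(second_windows(xy, 5.0), [[2.0, 0.0]])

    def test_partial_trailing_second_dropped(self, caplog):
        xy = np.zeros((13, 2))
        with caplog.at_level("WARNING"):
            out = second_windows(xy, 5.0)
        assert out.shape == (2, 2)
        assert "partial second" in caplog.text

    def test_speed_unit_conversion_and_first_second(self):
        xy = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 0.0]])
        speeds = movement_speed(xy)
        assert np.allclose(speeds, [3.6, 3.6, 0.0])

    def test_speed_needs_two_positions(self):
        with pytest.raises(InsufficientDataError):
            movement_speed(np.array([[0.0, 0.0]]))


class TestDistances:
    def test_signed_distance_to_target(self, pitch):
        assert distance_to_target(pitch.target_x - 40.0, pitch) == pytest.approx(40.0)
        assert distance_to_target(pitch.target_x, pitch) == pytest.approx(0.0)
        assert distance_to_target(pitch.target_x + 1.0, pitch) == pytest.approx(-1.0)

    def test_nearest_opponent_is_the_minimum(self):
        d = nearest_opponent_distance((0, 0), np.array([[3.0, 0.0], [0.0, 7.0]]))
        assert d == pytest.approx(3.0)

    def test_no_opponents_rejected(self):
        with pytest.raises(InsufficientDataError):
            nearest_opponent_distance((0, 0), np.empty((0, 2)))


class TestBinning:
    scheme = BinningScheme()

    def test_category_inventory_totals_37(self):
        assert self.scheme.n_categories == 37
        assert len(self.scheme.category_names()) == 37

    @pytest.mark.parametrize(
        "value,expected",
        [(40.0, 11), (37.45, 11), (22.0, 14), (0.0, 18), (-1.0, 19), (5.35, 17)],
    )
    def test_target_distance_bins(self, value, expected):
        assert self.scheme.bin_target_distance(value) == expected

    @pytest.mark.parametrize("value,expected", [(0.5, 20), (1.0, 21), (12.0, 31), (10.5, 30)])
    def test_opponent_distance_bins(self, value, expected):
        assert self.scheme.bin_opponent_distance(value) == expected

    @pytest.mark.parametrize(
        "value,expected",
        [(0.0, 32), (0.7, 33), (5.0, 34), (3.6, 34), (7.2, 35), (16.0, 36), (25.0, 37)],
    )
    def test_speed_bins_left_closed(self, value, expected):
        assert self.scheme.bin_speed(value) == expected

    def test_non_finite_value_rejected(self):
        with pytest.raises(EncodingError):
            self.scheme.bin_speed(np.nan)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        value=st.floats(-1e6, 1e6, allow_nan=False, allow_infinity=False),
        variable=st.sampled_from(["target", "opponent", "speed"]),
    )
    def test_binning_partitions_the_real_line(self, value, variable):
        ranges = {"target": range(11, 20), "opponent": range(20, 32), "speed": range(32, 38)}
        idx = self.scheme.bin_category(value, variable)
        assert idx in ranges[variable]

    def test_bins_are_monotone_in_value(self):
        values = np.sort(np.random.default_rng(2).uniform(-5, 50, 10000))
        assert (np.diff(self.scheme.bin_opponent_distance(values)) >= 0).all()
        assert (np.diff(self.scheme.bin_speed(values)) >= 0).all()
        assert (np.diff(self.scheme.bin_target_distance(values)) <= 0).all()


def _context(pitch):
    positions = {
        "A1": (10.0, 30.0),  # carrier
        "A2": (5.0, 28.0),   # behind, within support radius
        "A3": (20.0, 30.0),  # ahead of the ball
        "A4": (10.0, 50.0),  # lateral offset 20 m
        "A5": (0.0, 35.0),   # behind, outside support radius
        "D1": (13.0, 30.0),  # nearest defender, within press radius
        "D2": (15.0, 32.0),  # goal-side of D1, within cover radius
        "D3": (20.0, 55.0),  # goal-side but wide, not marking anyone
        "D4": (12.0, 35.0),  # goal-side of the ball inside the corridor
        "D5": (5.0, 29.0),   # marking A2
    }
    teams = {p: ("attack" if p.startswith("A") else "defend") for p in positions}
    return FrameContext(
        second=0, positions=positions, teams=teams, carrier="A1",
        pitch=pitch, thresholds=TacticalThresholds(),
    )


class TestTacticalRules:
    @pytest.mark.parametrize(
        "player,expected",
        [
            ("A1", 1),   # Penetration
            ("A2", 2),   # Offensive coverage
            ("A3", 3),   # Depth mobility
            ("A4", 4),   # Width and length
            ("A5", 5),   # Offensive unity
            ("D1", 6),   # Delay
            ("D2", 7),   # Defensive coverage
            ("D3", 10),  # Defensive unity
            ("D4", 9),   # Concentration
            ("D5", 8),   # Balance
        ],
    )
    def test_rule_table(self, pitch, player, expected):
        assert classify_tactical_action(_context(pitch), player) == expected

    def test_offensive_ids_only_for_carrier_team(self, pitch):
        ctx = _context(pitch)
        for p in ctx.positions:
            cat = classify_tactical_action(ctx, p)
            assert (cat <= 5) == (ctx.teams[p] == "attack")


class TestEncoding:
    def test_four_hot_invariant_over_a_full_trial(self, short_matrices):
        for cm in short_matrices.values():
            cm.validate()
            assert (cm.matrix.sum(axis=0) == 4).all()

    def test_encoding_is_deterministic(self, short_trial):
        cfg, tracks, events, _ = short_trial
        m1 = encode_player(tracks, events, "A3", cfg.pitch)
        m2 = encode_player(tracks, events, "A3", cfg.pitch)
        assert np.array_equal(m1.matrix, m2.matrix)

    def test_unknown_player_rejected(self, short_trial):
        cfg, tracks, events, _ = short_trial
        with pytest.raises(UnknownPlayerError):
            encode_player(tracks, events, "Z9", cfg.pitch)

    def test_stationary_far_player_has_constant_columns(self, pitch):
        frames = 50  # 10 s at 5 Hz
        times = np.repeat(np.arange(frames) / 5.0, 2)
        tracks = pd.DataFrame(
            {
                "time_s": times,
                "player": ["A1", "D1"] * frames,
                "team": ["attack", "defend"] * frames,
                "x_m": [5.0, 30.0] * frames,
                "y_m": [30.0, 55.0] * frames,
            }
        )
        events = pd.DataFrame(
            [[0.0, 10.0, "A1", "out_of_time", ""]],
            columns=["t_start_s", "t_end_s", "holder", "outcome", "receiver"],
        )
        cm = encode_player(tracks, events, "A1", pitch)
        assert (cm.matrix == cm.matrix[:, [0]]).all()
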