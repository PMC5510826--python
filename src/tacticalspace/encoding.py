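"""Configuration-state encoding.

Each player-second is described by a 37-component binary vector that is
4-hot: exactly one active category in each of four variable blocks —

====================================  =========  ==========================
variable                              categories  matrix rows (1-based ids)
====================================  =========  ==========================
tactical action                       10          1–10
distance from the target              9           11–19
distance from the nearest opponent    12          20–31
movement speed                        6           32–37
====================================  =========  ==========================

Distance-from-target categories descend from ``>37.45 m`` (id 11) in
contiguous 5.35 m steps down to ``0–5.35 m`` (id 18), with ``<0 m`` (id 19)
for positions past the target-zone boundary line. Opponent-distance
categories ascend from ``<1 m`` (id 20) in 1 m steps to ``>11 m`` (id 31).
Speed bands (km/h) are stand / walk / jog / medium- / high-intensity running
/ sprint. All intervals are closed on the left and open on the right so every
finite value maps to exactly one category.

A 5 Hz track is first passed through a two-frame moving-average filter, then
collapsed to one position per second (the mean of that second's frames);
speeds are taken between consecutive per-second positions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EncodingError, InsufficientDataError, InvalidStateError, UnknownPlayerError
from .pitch import Pitch
from .simulate import ATTACK_TEAM

logger = logging.getLogger(__name__)

TACTICAL_NAMES = (
    "Penetration",
    "Offensive coverage",
    "Depth mobility",
    "Width and length",
    "Offensive unity",
    "Delay",
    "Defensive coverage",
    "Balance",
    "Concentration",
    "Defensive unity",
)

# 1-based category ids of the four variable blocks
TACTICAL_IDS = range(1, 11)
TARGET_IDS = range(11, 20)
OPPONENT_IDS = range(20, 32)
SPEED_IDS = range(32, 38)

# matrix row slices (0-based) of the four blocks
TACTICAL_ROWS = slice(0, 10)
TARGET_ROWS = slice(10, 19)
OPPONENT_ROWS = slice(19, 31)
SPEED_ROWS = slice(31, 37)


@dataclass(frozen=True)
class BinningScheme:
    """Interval boundaries of the three continuous variables.

    Boundaries are ascending; intervals are ``[lower, upper)`` with the
    extremes open-ended. Target-distance categories are numbered in
    *descending* distance order (largest distance first), the other two in
    ascending order, matching the published category ids.
    """

    target_edges: tuple[float, ...] = (0.0, 5.35, 10.7, 16.05, 21.4, 26.75, 32.1, 37.45)
    opponent_edges: tuple[float, ...] = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11)
    speed_edges: tuple[float, ...] = (0.7, 3.6, 7.2, 14.4, 19.8)

    @property
    def n_categories(self) -> int:
        return (
            len(TACTICAL_NAMES)
            + (len(self.target_edges) + 1)
            + (len(self.opponent_edges) + 1)
            + (len(self.speed_edges) + 1)
        )

    def category_names(self) -> list[str]:
        """Names for all 37 categories in id order."""

        def intervals(edges, unit, reverse=False):
            lo = [f"<{edges[0]:g} {unit}"]
            mid = [f"{a:g}-{b:g} {unit}" for a, b in zip(edges[:-1], edges[1:])]
            hi = [f">{edges[-1]:g} {unit}"]
            names = lo + mid + hi
            return names[::-1] if reverse else names

        return (
            list(TACTICAL_NAMES)
            + intervals(self.target_edges, "m", reverse=True)
            + intervals(self.opponent_edges, "m")
            + intervals(self.speed_edges, "km/h")
        )

    # -- binning ------------------------------------------------------------

    def bin_target_distance(self, value):
        """Category id(s) 11..19 for signed distance-from-target in metres."""
        v = np.asarray(value, dtype=float)
        if not np.all(np.isfinite(v)):
            raise EncodingError("non-finite distance-from-target value")
        k = np.searchsorted(self.target_edges, v, side="right")
        out = 19 - k
        return int(out) if np.isscalar(value) else out

    def bin_opponent_distance(self, value):
        """Category id(s) 20..31 for nearest-opponent distance in metres."""
        v = np.asarray(value, dtype=float)
        if not np.all(np.isfinite(v)):
            raise EncodingError("non-finite opponent-distance value")
        k = np.searchsorted(self.opponent_edges, v, side="right")
        out = 20 + k
        return int(out) if np.isscalar(value) else out

    def bin_speed(self, value):
        """Category id(s) 32..37 for movement speed in km/h."""
        v = np.asarray(value, dtype=float)
        if not np.all(np.isfinite(v)):
            raise EncodingError("non-finite speed value")
        k = np.searchsorted(self.speed_edges, v, side="right")
        out = 32 + k
        return int(out) if np.isscalar(value) else out

    def bin_category(self, value: float, variable: str) -> int:
        """Dispatch by variable name: 'target', 'opponent' or 'speed'."""
        fns = {
            "target": self.bin_target_distance,
            "opponent": self.bin_opponent_distance,
            "speed": self.bin_speed,
        }
        if variable not in fns:
            raise EncodingError(f"unknown variable {variable!r}")
        return fns[variable](value)

    def hash(self) -> str:
        import hashlib

        payload = repr((self.target_edges, self.opponent_edges, self.speed_edges))
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class TacticalThresholds:
    """Metric thresholds of the tactical-action rule table (metres)."""

    press_radius: float = 5.0
    support_radius: float = 10.0
    cover_radius: float = 10.0
    width_threshold: float = 15.0
    corridor_halfwidth: float = 10.0
    marking_radius: float = 5.0


@dataclass
class FrameContext:
    """Everything needed to classify one second of play.

    ``positions`` maps player id -> (x, y); ``teams`` maps player id -> team
    label. ``carrier`` is None on a dead-ball second.
    """

    second: int
    positions: dict[str, tuple[float, float]]
    teams: dict[str, str]
    carrier: str | None
    pitch: Pitch
    thresholds: TacticalThresholds = field(default_factory=TacticalThresholds)


@dataclass
class ConfigurationMatrix:
    """Per-player binary configuration time series (37 rows x T seconds)."""

    player: str
    condition: str
    trial: int
    matrix: np.ndarray  # (37, T), uint8
    category_names: list[str]

    @property
    def n_seconds(self) -> int:
        return self.matrix.shape[1]

    def validate(self) -> None:
        m = self.matrix
        if m.shape[0] != 37 or not np.isin(m, (0, 1)).all():
            raise InvalidStateError("matrix must be 37 x T binary")
        for block in (TACTICAL_ROWS, TARGET_ROWS, OPPONENT_ROWS, SPEED_ROWS):
            if not (m[block].sum(axis=0) == 1).all():
                raise InvalidStateError("every column must be 1-hot within each variable block")

    def active_ids(self, second: int) -> tuple[int, ...]:
        """1-based category ids active at a given second."""
        return tuple(int(i) + 1 for i in np.flatnonzero(self.matrix[:, second]))


# ---------------------------------------------------------------------------
# track preprocessing


def smooth_track(xy: np.ndarray) -> np.ndarray:
    """Two-frame moving average: frame i is the mean of raw frames i-1 and i;
    frame 0 passes through."""
    xy = np.asarray(xy, dtype=float)
    if xy.ndim != 2 or len(xy) < 2:
        raise InsufficientDataError("smoothing needs at least two frames")
    out = xy.copy()
    out[1:] = 0.5 * (xy[:-1] + xy[1:])
    return out


def second_windows(xy: np.ndarray, rate_hz: float) -> np.ndarray:
    """Collapse a ``rate_hz`` track to one position per second (window mean).

    A trailing partial second is dropped with a logged warning.
    """
    xy = np.asarray(xy, dtype=float)
    r = int(round(rate_hz))
    if r <= 0:
        raise InsufficientDataError("rate must be positive")
    n_sec, rem = divmod(len(xy), r)
    if rem:
        logger.warning("dropping trailing partial second (%d of %d frames)", rem, r)
        xy = xy[: n_sec * r]
    if n_sec == 0:
        raise InsufficientDataError("fewer frames than one full second")
    return xy.reshape(n_sec, r, -1).mean(axis=1)


def movement_speed(per_second_xy: np.ndarray) -> np.ndarray:
    """Speed in km/h between consecutive per-second positions; the first
    second copies the second value."""
    xy = np.asarray(per_second_xy, dtype=float)
    if len(xy) < 2:
        raise InsufficientDataError("speed needs at least two per-second positions")
    disp = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    speeds = np.empty(len(xy))
    speeds[1:] = disp * 3.6  # m/s over 1 s -> km/h
    speeds[0] = speeds[1]
    return speeds


def distance_to_target(x, pitch: Pitch):
    """Signed longitudinal distance (m) from the target-zone boundary line;
    positive before the line, negative inside the target zone."""
    return pitch.target_x - np.asarray(x, dtype=float)


def nearest_opponent_distance(position, opponents: np.ndarray) -> float:
    """Minimum Euclidean distance from ``position`` to any opponent."""
    opp = np.atleast_2d(np.asarray(opponents, dtype=float))
    if opp.size == 0:
        raise InsufficientDataError("no opponents supplied")
    return float(np.min(np.linalg.norm(opp - np.asarray(position, dtype=float), axis=1)))


# ---------------------------------------------------------------------------
# tactical-action classification


def classify_tactical_action(ctx: FrameContext, player: str) -> int:
    """Assign one of the ten tactical-action categories (1-based id).

    Deterministic rule table over positions relative to the ball carrier.
    Attacking team (the carrier's team): Penetration for the carrier itself;
    Width and length beyond the lateral width threshold; Depth mobility when
    ahead of the ball toward the target; Offensive coverage when supporting
    within range behind the ball; Offensive unity otherwise. Defending team:
    Delay for the single nearest defender pressing the carrier; Defensive
    coverage goal-side of the delaying defender; Concentration goal-side of
    the ball inside the central corridor; Balance when marking some attacker;
    Defensive unity otherwise. Precedence is the listed order; the press
    tie-break is the first defender in iteration order.
    """
    if ctx.carrier is None:
        raise InvalidStateError("dead-ball second: no carrier in context")
    th = ctx.thresholds
    bx, by = ctx.positions[ctx.carrier]
    px, py = ctx.positions[player]
    attacking = ctx.teams[player] == ctx.teams[ctx.carrier]

    if attacking:
        if player == ctx.carrier:
            return 1  # Penetration
        if abs(py - by) > th.width_threshold:
            return 4  # Width and length
        if px > bx:
            return 3  # Depth mobility
        if np.hypot(px - bx, py - by) <= th.support_radius:
            return 2  # Offensive coverage
        return 5  # Offensive unity

    defenders = [p for p, t in ctx.teams.items() if t != ctx.teams[ctx.carrier]]
    ddists = {p: float(np.hypot(ctx.positions[p][0] - bx, ctx.positions[p][1] - by)) for p in defenders}
    delayer = min(defenders, key=lambda p: (ddists[p],)) if defenders else None
    if delayer is not None and ddists[delayer] > th.press_radius:
        delayer = None
    if player == delayer:
        return 6  # Delay
    if delayer is not None:
        dx, dy = ctx.positions[delayer]
        if px > dx and np.hypot(px - dx, py - dy) <= th.cover_radius:
            return 7  # Defensive coverage
    if px > bx and abs(py - ctx.pitch.width / 2.0) <= th.corridor_halfwidth:
        return 9  # Concentration
    attackers = [p for p, t in ctx.teams.items() if t == ctx.teams[ctx.carrier]]
    for a in attackers:
        ax, ay = ctx.positions[a]
        if np.hypot(px - ax, py - ay) <= th.marking_radius:
            return 8  # Balance
    return 10  # Defensive unity


# ---------------------------------------------------------------------------
# full encoding


def _per_second_positions(tracks: pd.DataFrame, rate_hz: float):
    """Smoothed per-second positions for every player in the tracks table."""
    players = list(pd.unique(tracks["player"]))
    teams = {}
    per_sec = {}
    for p in players:
        sub = tracks[tracks["player"] == p].sort_values("time_s")
        teams[p] = str(sub["team"].iloc[0])
        xy = sub[["x_m", "y_m"]].to_numpy()
        per_sec[p] = second_windows(smooth_track(xy), rate_hz)
    n_sec = min(len(v) for v in per_sec.values())
    per_sec = {p: v[:n_sec] for p, v in per_sec.items()}
    return players, teams, per_sec, n_sec


def _holder_per_second(events: pd.DataFrame, n_sec: int) -> list[str | None]:
    """Holder at each second's midpoint; None where no event covers it."""
    starts = events["t_start_s"].to_numpy(dtype=float)
    ends = events["t_end_s"].to_numpy(dtype=float)
    holders = events["holder"].to_numpy()
    mids = np.arange(n_sec) + 0.5
    idx = np.searchsorted(starts, mids, side="right") - 1
    out: list[str | None] = []
    for t, i in zip(mids, idx):
        out.append(str(holders[i]) if i >= 0 and t < ends[i] else None)
    return out


def encode_all(
    tracks: pd.DataFrame,
    events: pd.DataFrame,
    pitch: Pitch,
    scheme: BinningScheme | None = None,
    thresholds: TacticalThresholds | None = None,
    condition: str = "",
    trial: int = 0,
) -> dict[str, ConfigurationMatrix]:
    """Encode every player in ``tracks`` into a 37 x T configuration matrix.

    The sampling rate is inferred from the track time base. Dead-ball seconds
    (no possession event covering the second midpoint) carry the previous
    second's tactical category forward, with a logged notice.
    """
    scheme = scheme or BinningScheme()
    thresholds = thresholds or TacticalThresholds()
    t_unique = np.unique(tracks["time_s"].to_numpy(dtype=float))
    if len(t_unique) < 2:
        raise InsufficientDataError("tracks must span at least two frames")
    rate_hz = 1.0 / float(np.median(np.diff(t_unique)))

    players, teams, per_sec, n_sec = _per_second_positions(tracks, rate_hz)
    holder_sec = _holder_per_second(events, n_sec)

    speeds = {p: movement_speed(per_sec[p]) for p in players}
    n_cat = scheme.n_categories
    names = scheme.category_names()
    mats = {p: np.zeros((n_cat, n_sec), dtype=np.uint8) for p in players}
    prev_tactical: dict[str, int] = {}
    n_dead = 0

    for t in range(n_sec):
        positions = {p: tuple(per_sec[p][t]) for p in players}
        carrier = holder_sec[t]
        ctx = FrameContext(
            second=t, positions=positions, teams=teams, carrier=carrier,
            pitch=pitch, thresholds=thresholds,
        )
        by_team: dict[str, np.ndarray] = {}
        for team in set(teams.values()):
            by_team[team] = np.array([positions[p] for p in players if teams[p] == team])
        for p in players:
            if carrier is not None:
                tact = classify_tactical_action(ctx, p)
            else:
                n_dead += 1
                tact = prev_tactical.get(p, 5 if teams[p] == ATTACK_TEAM else 10)
            prev_tactical[p] = tact
            opp_team = next(tm for tm in by_team if tm != teams[p])
            d_target = float(distance_to_target(positions[p][0], pitch))
            d_opp = nearest_opponent_distance(positions[p], by_team[opp_team])
            m = mats[p]
            m[tact - 1, t] = 1
            m[scheme.bin_target_distance(d_target) - 1, t] = 1
            m[scheme.bin_opponent_distance(d_opp) - 1, t] = 1
            m[scheme.bin_speed(float(speeds[p][t])) - 1, t] = 1
    if n_dead:
        logger.info("carried tactical category forward on %d dead-ball player-seconds", n_dead)

    out = {}
    for p in players:
        cm = ConfigurationMatrix(
            player=p, condition=condition, trial=trial, matrix=mats[p], category_names=names
        )
        cm.validate()
        out[p] = cm
    return out


def encode_player(
    tracks: pd.DataFrame,
    events: pd.DataFrame,
    player: str,
    pitch: Pitch,
    scheme: BinningScheme | None = None,
    thresholds: TacticalThresholds | None = None,
    condition: str = "",
    trial: int = 0,
) -> ConfigurationMatrix:
    """Encode a single player (both teams' tracks are still required for the
    relative variables)."""
    if player not in set(tracks["player"]):
        raise UnknownPlayerError(f"player {player!r} absent from tracks")
    return encode_all(
        tracks, events, pitch, scheme, thresholds, condition=condition, trial=trial
    )[player]
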