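"""Synthetic constrained-match simulator.

Emulates the positional and notational data the analysis pipeline consumes:
10 attacking vs 9 defending outfield players, each anchored to one of nine
pitch sub-areas, playing 5-minute trials under one of three spatial-constraint
regimes:

- ``restricted`` — non-carriers may not leave their home sub-area;
- ``semi``       — non-carriers may roam their home sub-area plus all
                   (8-neighbour) adjacent sub-areas;
- ``free``       — non-carriers may roam the whole playing area.

The ball carrier is exempt from the constraint for the duration of their
possession and is additionally attracted toward the target point. Player
motion is a damped mean-reverting random walk around the home-zone centroid
(an Ornstein-Uhlenbeck-type scheme), with per-player activity levels spread
so that emitted speeds populate the encoding scheme's speed bands.

Ball events are generated as a possession chain: durations are exponential,
outcomes (pass to a specific teammate, turnover, goal) are drawn from a known
per-holder transition matrix which is returned as ground truth so that
downstream estimators can be validated by parameter recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .pitch import N_ZONES, Pitch, build_pitch

CONDITIONS = ("restricted", "semi", "free")

ATTACK_TEAM = "attack"
DEFEND_TEAM = "defend"

#: Sentinel outcome for a possession truncated by the trial end; downstream
#: possession statistics exclude it because its outcome is undefined.
OUT_OF_TIME = "out_of_time"
TERMINALS = ("turnover", "goal")

# Relative activity multipliers cycled over players so the emitted speed
# distribution spans from near-stationary to running.
_ACTIVITY_CYCLE = (0.25, 0.6, 1.0, 1.6, 0.4)


def default_players(n_attackers: int = 10, n_defenders: int = 9) -> tuple[list[str], list[str]]:
    attackers = [f"A{i}" for i in range(1, n_attackers + 1)]
    defenders = [f"D{i}" for i in range(1, n_defenders + 1)]
    return attackers, defenders


def default_home_zones(attackers: list[str], defenders: list[str]) -> dict[str, int]:
    """One player per zone; surplus players fill from the central zone."""
    homes: dict[str, int] = {}
    extras = [5, 2, 8, 4, 6]  # central then mid zones for surplus players
    for i, p in enumerate(attackers):
        homes[p] = i + 1 if i < N_ZONES else extras[(i - N_ZONES) % len(extras)]
    for i, p in enumerate(defenders):
        homes[p] = i + 1 if i < N_ZONES else extras[(i - N_ZONES) % len(extras)]
    return homes


def default_transition_matrix(
    attackers: list[str],
    home_zones: dict[str, int],
    pitch: Pitch,
    turnover_p: float = 0.13,
    goal_p_front: float = 0.06,
    goal_p_back: float = 0.02,
) -> pd.DataFrame:
    """Row-stochastic holder -> outcome matrix over teammates + {turnover, goal}.

    Passes favour teammates anchored in the same or an adjacent sub-area
    (weight 2 vs 1), goals are more probable for holders anchored in the
    column nearest the target.
    """
    cols = list(attackers) + ["turnover", "goal"]
    rows = []
    for h in attackers:
        hz = home_zones[h]
        front = (hz - 1) % 3 == 2  # column nearest the target line
        gp = goal_p_front if front else goal_p_back
        weights = np.zeros(len(cols))
        for j, t in enumerate(attackers):
            if t == h:
                continue
            tz = home_zones[t]
            weights[j] = 2.0 if (tz == hz or tz in pitch.neighbors(hz)) else 1.0
        weights *= (1.0 - turnover_p - gp) / weights.sum()
        weights[-2] = turnover_p
        weights[-1] = gp
        rows.append(weights)
    mat = pd.DataFrame(rows, index=attackers, columns=cols)
    # exact normalization against float drift
    mat = mat.div(mat.sum(axis=1), axis=0)
    return mat


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterization of one simulated trial."""

    condition: str = "restricted"
    n_attackers: int = 10
    n_defenders: int = 9
    duration_s: float = 300.0
    rate_hz: float = 5.0
    seed: int = 0
    pitch: Pitch = field(default_factory=build_pitch)
    home_zones: dict[str, int] | None = None
    anchor_strength: float = 1.2      # 1/s, pull toward home centroid
    noise_scale: float = 1.8          # m / sqrt(s), base diffusion
    max_speed_mps: float = 8.0
    carrier_speed_mps: float = 4.5    # drift of the carrier toward the target
    possession_mean_s: float = 3.0
    transition: pd.DataFrame | None = None

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise ConfigurationError(
                f"unknown condition {self.condition!r}; expected one of {CONDITIONS}"
            )
        if self.duration_s <= 0:
            raise ConfigurationError("duration_s must be positive")
        if self.rate_hz <= 0:
            raise ConfigurationError("rate_hz must be positive")
        if self.possession_mean_s <= 0:
            raise ConfigurationError("possession_mean_s must be positive")

    def resolve(self) -> "SimulationConfig":
        """Fill derived defaults (home zones, transition matrix); validate."""
        attackers, defenders = default_players(self.n_attackers, self.n_defenders)
        homes = dict(self.home_zones) if self.home_zones is not None else default_home_zones(
            attackers, defenders
        )
        for p in attackers + defenders:
            if p not in homes:
                raise ConfigurationError(f"player {p} has no home sub-area")
            if not 1 <= homes[p] <= N_ZONES:
                raise ConfigurationError(f"player {p} home zone {homes[p]} outside 1..{N_ZONES}")
        trans = (
            self.transition
            if self.transition is not None
            else default_transition_matrix(attackers, homes, self.pitch)
        )
        row_sums = trans.sum(axis=1).to_numpy()
        if not np.allclose(row_sums, 1.0, atol=1e-12):
            raise ConfigurationError("transition matrix rows must sum to 1 within 1e-12")
        return replace(self, home_zones=homes, transition=trans)


@dataclass(frozen=True)
class GroundTruth:
    """Generator parameters actually used by a simulation run."""

    transition: pd.DataFrame
    possession_mean_s: float
    home_zones: dict[str, int]


def _possession_chain(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    attackers, _ = default_players(cfg.n_attackers, cfg.n_defenders)
    cols = list(cfg.transition.columns)
    probs = cfg.transition.to_numpy()
    idx = {p: i for i, p in enumerate(attackers)}
    records = []
    t = 0.0
    holder = attackers[rng.integers(len(attackers))]
    while t < cfg.duration_s:
        dur = rng.exponential(cfg.possession_mean_s)
        end = t + dur
        if end >= cfg.duration_s:
            records.append((t, cfg.duration_s, holder, OUT_OF_TIME, ""))
            break
        outcome = cols[rng.choice(len(cols), p=probs[idx[holder]])]
        if outcome in TERMINALS:
            records.append((t, end, holder, outcome, ""))
            holder = attackers[rng.integers(len(attackers))]
        else:
            records.append((t, end, holder, "pass", outcome))
            holder = outcome
        t = end
    return pd.DataFrame(
        records, columns=["t_start_s", "t_end_s", "holder", "outcome", "receiver"]
    )


def _reflect(x: float, lo: float, hi: float) -> float:
    """Fold a coordinate back into [lo, hi] by boundary reflection."""
    if lo >= hi:
        return lo
    span = hi - lo
    x = (x - lo) % (2.0 * span)
    if x > span:
        x = 2.0 * span - x
    return x + lo


def simulate_match(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate one trial.

    Returns
    -------
    tracks:
        ``time_s, player, team, x_m, y_m`` at ``rate_hz`` for every outfield
        player; ``duration_s * rate_hz`` frames per player.
    events:
        ``t_start_s, t_end_s, holder, outcome, receiver`` possession intervals
        partitioning the trial (half-open, outcome of the final truncated
        possession is ``out_of_time``).
    truth:
        The transition matrix, possession-duration mean and home assignment
        used, for parameter-recovery checks.
    """
    cfg = config.resolve()
    rng = np.random.default_rng(cfg.seed)
    pitch = cfg.pitch
    attackers, defenders = default_players(cfg.n_attackers, cfg.n_defenders)
    players = attackers + defenders
    teams = [ATTACK_TEAM] * len(attackers) + [DEFEND_TEAM] * len(defenders)
    n = len(players)

    events = _possession_chain(cfg, rng)

    n_frames = int(round(cfg.duration_s * cfg.rate_hz))
    dt = 1.0 / cfg.rate_hz
    sdt = math.sqrt(dt)

    # holder index per frame (attacker index), from half-open event intervals
    holder_of_frame = np.empty(n_frames, dtype=int)
    a_idx = {p: i for i, p in enumerate(attackers)}
    ev = events.to_numpy()
    times = np.arange(n_frames) * dt
    ei = 0
    for f, t in enumerate(times):
        while ei + 1 < len(ev) and t >= ev[ei][1]:
            ei += 1
        holder_of_frame[f] = a_idx[ev[ei][2]]

    rects = np.array(
        [pitch.permitted_rect(cfg.home_zones[p], cfg.condition) for p in players]
    )  # (n, 4): x0, x1, y0, y1
    anchors = np.array([pitch.zone_centroid(cfg.home_zones[p]) for p in players])
    activity = np.array([_ACTIVITY_CYCLE[i % len(_ACTIVITY_CYCLE)] for i in range(n)])
    noise = cfg.noise_scale * activity
    tx, ty = pitch.target_point
    carrier_hi_x = pitch.length + pitch.target_depth

    pos = anchors.copy()
    out = np.empty((n_frames, n, 2))
    prev_carrier = -1
    max_step = cfg.max_speed_mps * dt
    for f in range(n_frames):
        carrier = holder_of_frame[f]
        if prev_carrier >= 0 and carrier != prev_carrier:
            # ex-carrier re-enters their permitted region instantly
            x0, x1, y0, y1 = rects[prev_carrier]
            pos[prev_carrier, 0] = min(max(pos[prev_carrier, 0], x0), x1)
            pos[prev_carrier, 1] = min(max(pos[prev_carrier, 1], y0), y1)
        step = cfg.anchor_strength * (anchors - pos) * dt
        step += rng.normal(size=(n, 2)) * (noise[:, None] * sdt)
        # carrier: drift toward the target point instead of the home anchor
        d = np.array([tx, ty]) - pos[carrier]
        dist = float(np.hypot(*d))
        drift = cfg.carrier_speed_mps * d / dist * dt if dist > 1e-9 else 0.0
        step[carrier] = drift + rng.normal(size=2) * (noise[carrier] * sdt)
        # speed cap
        norms = np.hypot(step[:, 0], step[:, 1])
        over = norms > max_step
        step[over] *= (max_step / norms[over])[:, None]
        pos = pos + step
        # constraint enforcement by reflection; the carrier may use the whole
        # pitch including the target zone
        for i in range(n):
            if i == carrier:
                pos[i, 0] = _reflect(pos[i, 0], 0.0, carrier_hi_x)
                pos[i, 1] = _reflect(pos[i, 1], 0.0, pitch.width)
            else:
                x0, x1, y0, y1 = rects[i]
                pos[i, 0] = _reflect(pos[i, 0], x0, x1)
                pos[i, 1] = _reflect(pos[i, 1], y0, y1)
        out[f] = pos
        prev_carrier = carrier

    tracks = pd.DataFrame(
        {
            "time_s": np.repeat(times, n),
            "player": np.tile(players, n_frames),
            "team": np.tile(teams, n_frames),
            "x_m": out[:, :, 0].ravel(),
            "y_m": out[:, :, 1].ravel(),
        }
    )
    truth = GroundTruth(
        transition=cfg.transition.copy(),
        possession_mean_s=cfg.possession_mean_s,
        home_zones=dict(cfg.home_zones),
    )
    return tracks, events, truth


def holder_at(events: pd.DataFrame, t: float) -> str | None:
    """Holder of the ball at time ``t`` under half-open [start, end) intervals."""
    sel = events[(events["t_start_s"] <= t) & (t < events["t_end_s"])]
    if sel.empty:
        return None
    return str(sel.iloc[0]["holder"])
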