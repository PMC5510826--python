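"""End-to-end orchestration: simulate → encode → analyse → compare → report.

``run_pipeline`` drives the whole study design: for each constraint
condition it simulates (or is given) repeated trials, encodes every player
into configuration matrices, pools each player's overlap curves across
trials and fits the relaxation law, builds the condition's passing network
and carrier potential landscape, and finally produces a condition-comparison
report (percent differences with 90% CL, Cohen's d, qualitative chances,
chi-square on the frequency grids). All randomness is derived from
``base_seed``; re-running an identical configuration reproduces every output
bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .ballflow import PassingNetwork, network_to_dict, possession_summary, transition_matrix
from .encoding import BinningScheme, TacticalThresholds, encode_all
from .errors import PipelineStageError
from .exploration import OverlapFit, dynamic_overlap, fit_overlap_model, pool_curves
from .landscape import StateGrid, carrier_states, landscape_table, occupancy_grid, potential_landscape
from .mbi import chi_square_compare, mbi_compare
from .pitch import Pitch, build_pitch
from .simulate import CONDITIONS, SimulationConfig, simulate_match

logger = logging.getLogger(__name__)

#: comparison pairs in the conventional a/b/c order
DEFAULT_PAIRS = (("restricted", "semi"), ("restricted", "free"), ("semi", "free"))

_LOG_FLOOR = 1e-6  # guards the log transform for fitted values at zero
_COUNT_OFFSET = 1.0  # added to count-valued cells before the log transform


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full pipeline run."""

    conditions: tuple[str, ...] = CONDITIONS
    trials_per_condition: int = 2
    base_seed: int = 0
    duration_s: float = 300.0
    rate_hz: float = 5.0
    n_attackers: int = 10
    n_defenders: int = 9
    max_lag: int | None = None
    epsilon: float = 0.05
    out_dir: str | None = None
    pitch: Pitch = field(default_factory=build_pitch)
    scheme: BinningScheme = field(default_factory=BinningScheme)
    thresholds: TacticalThresholds = field(default_factory=TacticalThresholds)

    def seed_for(self, condition: str, trial: int) -> int:
        return self.base_seed + 1000 * self.conditions.index(condition) + trial

    def to_dict(self) -> dict:
        return {
            "conditions": list(self.conditions),
            "trials_per_condition": self.trials_per_condition,
            "base_seed": self.base_seed,
            "duration_s": self.duration_s,
            "rate_hz": self.rate_hz,
            "n_attackers": self.n_attackers,
            "n_defenders": self.n_defenders,
            "max_lag": self.max_lag,
            "epsilon": self.epsilon,
            "pitch": [self.pitch.length, self.pitch.width, self.pitch.target_depth],
            "scheme_hash": self.scheme.hash(),
            "thresholds": vars(self.thresholds),
        }

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_mapping(cls, data: dict) -> "RunConfig":
        kwargs = dict(data)
        if "conditions" in kwargs:
            kwargs["conditions"] = tuple(kwargs["conditions"])
        if "pitch" in kwargs:
            kwargs["pitch"] = build_pitch(*kwargs["pitch"])
        if "thresholds" in kwargs:
            kwargs["thresholds"] = TacticalThresholds(**kwargs["thresholds"])
        kwargs.pop("scheme_hash", None)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        return cls.from_mapping(yaml.safe_load(Path(path).read_text()))

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls.from_mapping(json.loads(Path(path).read_text()))


@dataclass
class ConditionResult:
    """Everything computed for one constraint condition."""

    condition: str
    fits: dict[str, OverlapFit]                     # per player, trial-pooled
    network: PassingNetwork
    grid: StateGrid
    landscape_table: pd.DataFrame
    possession_samples: list[float]                 # per holder per trial
    pooled_possession_mean_s: float
    compliance: float                               # non-carrier frames in bounds


@dataclass
class PipelineResult:
    config: RunConfig
    conditions: dict[str, ConditionResult]
    fits_table: pd.DataFrame
    report: pd.DataFrame
    chi_square: pd.DataFrame
    manifest: dict


def constraint_compliance(tracks: pd.DataFrame, events: pd.DataFrame, cfg: SimulationConfig) -> float:
    """Fraction of non-carrier frames inside the permitted region."""
    sim = cfg.resolve()
    pitch = sim.pitch
    starts = events["t_start_s"].to_numpy(dtype=float)
    ends = events["t_end_s"].to_numpy(dtype=float)
    holders = events["holder"].to_numpy()
    ok = total = 0
    for player, sub in tracks.groupby("player", sort=False):
        x = sub["x_m"].to_numpy()
        y = sub["y_m"].to_numpy()
        t = sub["time_s"].to_numpy()
        idx = np.searchsorted(starts, t, side="right") - 1
        is_carrier = np.zeros(len(t), dtype=bool)
        valid = idx >= 0
        is_carrier[valid] = (holders[idx[valid]] == player) & (t[valid] < ends[idx[valid]])
        x0, x1, y0, y1 = pitch.permitted_rect(sim.home_zones[player], sim.condition)
        tol = 1e-9
        inside = (x >= x0 - tol) & (x <= x1 + tol) & (y >= y0 - tol) & (y <= y1 + tol)
        mask = ~is_carrier
        ok += int(np.count_nonzero(inside & mask))
        total += int(np.count_nonzero(mask))
    return ok / total if total else 1.0


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                result = fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-tag with the stage name
                raise PipelineStageError(name, str(exc)) from exc
            logger.info("stage %s finished in %.2f s", name, time.perf_counter() - t0)
            return result

        return wrapper

    return deco


@_stage("simulate")
def _simulate_trial(run: RunConfig, condition: str, trial: int):
    cfg = SimulationConfig(
        condition=condition,
        n_attackers=run.n_attackers,
        n_defenders=run.n_defenders,
        duration_s=run.duration_s,
        rate_hz=run.rate_hz,
        seed=run.seed_for(condition, trial),
        pitch=run.pitch,
    )
    tracks, events, truth = simulate_match(cfg)
    return cfg, tracks, events, truth


@_stage("encode")
def _encode_trial(run: RunConfig, condition: str, trial: int, tracks, events):
    return encode_all(
        tracks, events, run.pitch, run.scheme, run.thresholds,
        condition=condition, trial=trial,
    )


def run_condition(run: RunConfig, condition: str) -> ConditionResult:
    """Simulate and analyse all trials of one condition."""
    per_player_curves: dict[str, list] = {}
    all_events = []
    all_states = []
    possession_samples: list[float] = []
    compliances = []
    for trial in range(run.trials_per_condition):
        cfg, tracks, events, _ = _simulate_trial(run, condition, trial)
        matrices = _encode_trial(run, condition, trial, tracks, events)
        compliances.append(constraint_compliance(tracks, events, cfg))
        for player, cm in matrices.items():
            per_player_curves.setdefault(player, []).append(
                dynamic_overlap(cm, max_lag=run.max_lag)
            )
        all_events.append(events)
        all_states.extend(carrier_states(events, matrices))
        per_holder, _ = possession_summary(events)
        possession_samples.extend(float(v) for v in per_holder.dropna())

    fits = {
        player: fit_overlap_model(pool_curves(curves), epsilon=run.epsilon)
        for player, curves in per_player_curves.items()
    }
    events_pooled = pd.concat(all_events, ignore_index=True)
    attackers = [f"A{i}" for i in range(1, run.n_attackers + 1)]
    network = transition_matrix(events_pooled, players=attackers)
    _, pooled_mean = possession_summary(events_pooled)
    grid = occupancy_grid(all_states)
    land = potential_landscape(grid)
    return ConditionResult(
        condition=condition,
        fits=fits,
        network=network,
        grid=grid,
        landscape_table=landscape_table(grid, land, run.scheme),
        possession_samples=possession_samples,
        pooled_possession_mean_s=pooled_mean,
        compliance=float(np.mean(compliances)),
    )


def _interaction_cells(network: PassingNetwork) -> np.ndarray:
    """The 110 passing-interaction cells: holders x (teammates + sinks),
    self-pass column excluded."""
    vals = []
    for h in network.players:
        for c in network.counts.columns:
            if c != h:
                vals.append(int(network.counts.loc[h, c]))
    return np.array(vals, dtype=float)


def _comparison_rows(results: dict[str, ConditionResult], pairs) -> tuple[pd.DataFrame, pd.DataFrame]:
    rows = []
    chi_rows = []

    def samples(cond: str) -> dict[str, np.ndarray]:
        r = results[cond]
        fits = list(r.fits.values())
        return {
            "possession_dt_s": np.asarray(r.possession_samples),
            "passing_interactions": _interaction_cells(r.network) + _COUNT_OFFSET,
            "configuration_space": r.grid.counts.ravel().astype(float) + _COUNT_OFFSET,
            "q_stat": np.array([max(f.q_stat, _LOG_FLOOR) for f in fits]),
            "alpha": np.array([max(f.alpha, _LOG_FLOOR) for f in fits if np.isfinite(f.alpha)]),
            "t_star": np.array([max(f.t_star, _LOG_FLOOR) for f in fits]),
        }

    cache = {c: samples(c) for c in results}
    for a, b in pairs:
        if a not in results or b not in results:
            continue
        for variable in cache[a]:
            rep = mbi_compare(cache[a][variable], cache[b][variable])
            rows.append(
                {
                    "variable": variable,
                    "comparison": f"{a} vs {b}",
                    "percent_diff": rep.percent_diff,
                    "percent_cl": rep.percent_cl,
                    "chance_smaller": rep.chance_smaller,
                    "chance_similar": rep.chance_similar,
                    "chance_greater": rep.chance_greater,
                    "qualitative": rep.qualitative,
                    "cohens_d": rep.cohens_d,
                    "d_cl": rep.d_cl,
                    "magnitude": rep.magnitude,
                }
            )
        fc = chi_square_compare(
            results[a].grid.counts.ravel(), results[b].grid.counts.ravel()
        )
        chi_rows.append(
            {
                "variable": "configuration_space",
                "comparison": f"{a} vs {b}",
                "chi2": fc.chi2,
                "df": fc.df,
                "p_value": fc.p_value,
                "eta_squared": fc.eta_squared,
            }
        )
    return pd.DataFrame(rows), pd.DataFrame(chi_rows)


def run_pipeline(run: RunConfig) -> PipelineResult:
    """Execute the full study pipeline; optionally write a result bundle.

    When ``run.out_dir`` is set, writes per-condition network JSON and
    landscape CSVs, the pooled fits table, the comparison report and a
    manifest tying every output to the configuration hash and seeds.
    """
    t0 = time.perf_counter()
    results = {c: run_condition(run, c) for c in run.conditions}

    fit_rows = [
        {
            "player": player,
            "condition": c,
            "q_stat": f.q_stat,
            "alpha": f.alpha,
            "t_star": f.t_star,
            "rss": f.rss,
            "converged": f.converged,
        }
        for c, res in results.items()
        for player, f in res.fits.items()
    ]
    fits_table = pd.DataFrame(fit_rows)
    report, chi = _comparison_rows(results, DEFAULT_PAIRS)

    manifest = {
        "package_version": __version__,
        "config": run.to_dict(),
        "config_hash": run.hash(),
        "seeds": {
            c: [run.seed_for(c, t) for t in range(run.trials_per_condition)]
            for c in run.conditions
        },
        "runtime_s": round(time.perf_counter() - t0, 3),
    }

    if run.out_dir is not None:
        out = Path(run.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        fits_table.to_csv(out / "fits.csv", index=False)
        report.to_csv(out / "report.csv", index=False)
        chi.to_csv(out / "chi_square.csv", index=False)
        for c, res in results.items():
            (out / f"network_{c}.json").write_text(
                json.dumps(network_to_dict(res.network), indent=2)
            )
            res.landscape_table.to_csv(out / f"landscape_{c}.csv", index=False)
        manifest_path = out / "manifest.json"
        stable = {k: v for k, v in manifest.items() if k != "runtime_s"}
        manifest_path.write_text(json.dumps(stable, indent=2, sort_keys=True))

    return PipelineResult(
        config=run,
        conditions=results,
        fits_table=fits_table,
        report=report,
        chi_square=chi,
        manifest=manifest,
    )
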