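"""Ball-flow dynamics: possession durations and the pass-transition network.

A player "interaction" is any completed possession outcome — a pass to a
teammate, a turnover, or a goal. The transition matrix has one row per
holder and one column per teammate plus the two absorbing outcomes; each
row divides the holder's outcome counts by their total interactions, so
populated rows are stochastic. A possession truncated by the trial end has
an undefined outcome and is excluded from both counts and durations.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .errors import InsufficientDataError
from .simulate import OUT_OF_TIME

logger = logging.getLogger(__name__)

SINKS = ("turnover", "goal")


@dataclass
class PassingNetwork:
    """Transition structure of ball flow within the analyzed team."""

    players: list[str]
    mean_possession_s: pd.Series      # per holder
    counts: pd.DataFrame              # holders x (teammates + sinks), raw
    probabilities: pd.DataFrame       # row-normalized where populated
    zero_rows: list[str]              # holders with no completed interaction

    @property
    def n_interactions(self) -> int:
        return int(self.counts.to_numpy().sum())

    def graph(self) -> nx.DiGraph:
        """Directed graph with probability-weighted edges (sinks included)."""
        g = nx.DiGraph()
        g.add_nodes_from(self.players)
        g.add_nodes_from(SINKS)
        for h in self.players:
            for c in self.probabilities.columns:
                p = float(self.probabilities.loc[h, c])
                if p > 0:
                    g.add_edge(h, c, probability=p, count=int(self.counts.loc[h, c]))
        return g


def completed_events(events: pd.DataFrame) -> pd.DataFrame:
    """Events with a defined outcome (trailing truncated possession dropped)."""
    return events[events["outcome"] != OUT_OF_TIME]


def possession_summary(events: pd.DataFrame) -> tuple[pd.Series, float]:
    """Per-holder and pooled mean possession duration in seconds."""
    ev = completed_events(events)
    if ev.empty:
        raise InsufficientDataError("no completed possession events")
    dur = ev["t_end_s"] - ev["t_start_s"]
    per_holder = dur.groupby(ev["holder"]).mean()
    return per_holder, float(dur.mean())


def transition_matrix(events: pd.DataFrame, players: list[str] | None = None) -> PassingNetwork:
    """Estimate the holder -> outcome transition matrix from an event log."""
    ev = completed_events(events)
    if ev.empty:
        raise InsufficientDataError("no completed possession events")
    if players is None:
        players = sorted(set(ev["holder"]) | set(ev.loc[ev["outcome"] == "pass", "receiver"]))
    cols = list(players) + list(SINKS)
    counts = pd.DataFrame(0, index=list(players), columns=cols, dtype=int)
    for _, row in ev.iterrows():
        dest = row["receiver"] if row["outcome"] == "pass" else row["outcome"]
        counts.loc[row["holder"], dest] += 1
    totals = counts.sum(axis=1)
    zero_rows = [h for h in players if totals[h] == 0]
    if zero_rows:
        logger.warning("holders with zero interactions: %s", zero_rows)
    probs = counts.astype(float)
    populated = totals > 0
    probs.loc[populated] = probs.loc[populated].div(totals[populated], axis=0)
    per_holder, _ = possession_summary(events)
    per_holder = per_holder.reindex(players)
    return PassingNetwork(
        players=list(players),
        mean_possession_s=per_holder,
        counts=counts,
        probabilities=probs,
        zero_rows=zero_rows,
    )


def probable_channels(
    network: PassingNetwork,
    sources: list[str],
    sink: str = "goal",
    k: int = 5,
    max_len: int = 6,
) -> list[tuple[list[str], float]]:
    """The k most probable loop-free holder sequences from a source to the sink.

    Paths are ranked by the product of edge probabilities, computed by
    exhaustive loop-free enumeration up to ``max_len`` intermediate hops;
    ties break lexicographically on the node sequence. An unreachable sink
    yields an empty list with a warning.
    """
    g = network.graph()
    found: list[tuple[list[str], float]] = []
    for src in sources:
        if src not in g:
            continue
        for path in nx.all_simple_paths(g, src, sink, cutoff=max_len):
            prob = 1.0
            for a, b in itertools.pairwise(path):
                prob *= g[a][b]["probability"]
            found.append((list(path), prob))
    if not found:
        logger.warning("sink %r unreachable from sources %s", sink, sources)
        return []
    found.sort(key=lambda pr: (-pr[1], pr[0]))
    return found[:k]


def network_to_dict(network: PassingNetwork) -> dict:
    """JSON-serializable view: nodes with possession stats, edges with
    counts and probabilities."""
    nodes = [
        {
            "id": h,
            "mean_possession_s": None
            if pd.isna(network.mean_possession_s.get(h))
            else float(network.mean_possession_s[h]),
            "n_interactions": int(network.counts.loc[h].sum()),
        }
        for h in network.players
    ]
    edges = [
        {
            "from": h,
            "to": c,
            "count": int(network.counts.loc[h, c]),
            "probability": float(network.probabilities.loc[h, c]),
        }
        for h in network.players
        for c in network.counts.columns
        if network.counts.loc[h, c] > 0
    ]
    return {"nodes": nodes, "edges": edges}
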