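"""Potential landscape of the ball carrier's configuration space.

The carrier's state each second is the pair (distance-from-target bin,
nearest-opponent-distance bin): a 9 x 12 = 108-cell grid. Occupancy
probabilities are relative frequencies p_i = n_i / N over carrier-seconds,
and each occupied cell receives a potential

    V_i = -Q * ln(p_i * C)        (default, sign="well")
    V_i = +Q * ln(p_i * C)        (sign="printed")

where C = 108 is the number of configurations in the spanned space and
Q = 1 a standardized variance term. Under the default sign high-probability
(stable) states are deep wells; the printed sign inverts the surface. Cells
never visited are masked rather than assigned infinite potential.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .encoding import ConfigurationMatrix, OPPONENT_ROWS, TARGET_ROWS
from .encoding import _holder_per_second  # shared second->holder resolution
from .errors import InsufficientDataError

logger = logging.getLogger(__name__)

N_TARGET_BINS = 9
N_OPPONENT_BINS = 12
N_CELLS = N_TARGET_BINS * N_OPPONENT_BINS  # 108


@dataclass
class StateGrid:
    """Occupancy counts over the carrier's 2D configuration space."""

    counts: np.ndarray  # (9, 12) int, [target bin offset, opponent bin offset]

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (N_TARGET_BINS, N_OPPONENT_BINS):
            raise ValueError(f"grid must be {N_TARGET_BINS} x {N_OPPONENT_BINS}")

    @property
    def n_observations(self) -> int:
        return int(self.counts.sum())

    @property
    def n_cells(self) -> int:
        return N_CELLS


@dataclass
class PotentialLandscape:
    """Occupancy probabilities and potentials over the state grid."""

    probabilities: np.ndarray  # (9, 12) float, sums to 1
    potential: np.ndarray      # (9, 12) float, NaN on masked cells
    mask: np.ndarray           # (9, 12) bool, True where the cell is empty
    q_term: float
    sign: str


def carrier_states(
    events: pd.DataFrame,
    matrices: dict[str, ConfigurationMatrix],
) -> list[tuple[int, int]]:
    """Per-second (target-bin, opponent-bin) pairs of the ball carrier.

    Bin offsets are 0-based within each block (0..8 and 0..11). Seconds whose
    holder has no encoded matrix are skipped with a logged gap count.
    """
    if not matrices:
        raise InsufficientDataError("no configuration matrices supplied")
    n_sec = min(m.n_seconds for m in matrices.values())
    holders = _holder_per_second(events, n_sec)
    states: list[tuple[int, int]] = []
    n_gaps = 0
    for t, h in enumerate(holders):
        if h is None or h not in matrices:
            n_gaps += 1
            continue
        m = matrices[h].matrix
        tbin = int(np.argmax(m[TARGET_ROWS, t]))
        obin = int(np.argmax(m[OPPONENT_ROWS, t]))
        states.append((tbin, obin))
    if n_gaps:
        logger.info("skipped %d seconds without an encoded carrier", n_gaps)
    return states


def occupancy_grid(states: list[tuple[int, int]]) -> StateGrid:
    """Tally carrier states into the 9 x 12 grid."""
    if not states:
        raise InsufficientDataError("empty carrier-state sequence")
    counts = np.zeros((N_TARGET_BINS, N_OPPONENT_BINS), dtype=int)
    for tbin, obin in states:
        counts[tbin, obin] += 1
    return StateGrid(counts=counts)


def potential_landscape(grid: StateGrid, q_term: float = 1.0, sign: str = "well") -> PotentialLandscape:
    """Transform occupancy counts into a potential surface.

    ``sign="well"`` (default) gives V = -Q ln(p C): frequent states are
    minima (wells). ``sign="printed"`` gives V = +Q ln(p C). Empty cells are
    masked (NaN), never infinite.
    """
    if q_term <= 0:
        raise ValueError("q_term must be positive")
    if sign not in ("well", "printed"):
        raise ValueError(f"sign must be 'well' or 'printed', got {sign!r}")
    n = grid.n_observations
    if n == 0:
        raise InsufficientDataError("grid has no observations")
    p = grid.counts / n
    mask = grid.counts == 0
    v = np.full(p.shape, np.nan)
    occupied = ~mask
    core = q_term * np.log(p[occupied] * grid.n_cells)
    v[occupied] = -core if sign == "well" else core
    return PotentialLandscape(probabilities=p, potential=v, mask=mask, q_term=q_term, sign=sign)


def landscape_table(grid: StateGrid, land: PotentialLandscape, scheme=None) -> pd.DataFrame:
    """Long-format table: one row per cell with count, probability, potential."""
    from .encoding import BinningScheme

    scheme = scheme or BinningScheme()
    names = scheme.category_names()
    target_names = names[10:19]
    opp_names = names[19:31]
    rows = []
    for i in range(N_TARGET_BINS):
        for j in range(N_OPPONENT_BINS):
            rows.append(
                {
                    "target_bin": target_names[i],
                    "opponent_bin": opp_names[j],
                    "count": int(grid.counts[i, j]),
                    "probability": float(land.probabilities[i, j]),
                    "potential": float(land.potential[i, j]),
                    "masked": bool(land.mask[i, j]),
                }
            )
    return pd.DataFrame(rows)
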