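"""Pitch geometry: the playing area, its 3x3 sub-area partition and the target.

Coordinates are metres. The playing area is the rectangle
``[0, length] x [0, width]`` between the penalty-area edge (x = 0) and the
target-zone boundary line (x = length); +x is the attacking direction of the
analyzed team. The target zone extends ``target_depth`` metres beyond the
boundary line, and the target point sits at the centre of that line.

Sub-areas are indexed 1..9 in row-major order: index 1 is the corner nearest
the origin, columns advance along +x (toward the target), rows along +y.
Adjacency between sub-areas is 8-neighbour (edge- or corner-sharing).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidGeometryError

N_ZONE_COLS = 3
N_ZONE_ROWS = 3
N_ZONES = N_ZONE_COLS * N_ZONE_ROWS


def _zone_rc(zone: int) -> tuple[int, int]:
    """Row/column (0-based) of a 1-based zone index."""
    if not 1 <= zone <= N_ZONES:
        raise InvalidGeometryError(f"zone index {zone} outside 1..{N_ZONES}")
    return (zone - 1) // N_ZONE_COLS, (zone - 1) % N_ZONE_COLS


@dataclass(frozen=True)
class Pitch:
    """Playing area geometry with its 3x3 sub-area tiling.

    Parameters
    ----------
    length:
        Longitudinal extent of the playing area (penalty-area edge to the
        target-zone boundary line), metres.
    width:
        Lateral extent, metres.
    target_depth:
        Depth of the target zone beyond the boundary line, metres. The ball
        carrier may enter it; sub-areas do not cover it.
    """

    length: float = 37.5
    width: float = 60.0
    target_depth: float = 5.0
    adjacency: dict[int, frozenset[int]] = field(init=False, repr=False)

    def __post_init__(self):
        if self.length <= 0 or self.width <= 0 or self.target_depth <= 0:
            raise InvalidGeometryError(
                f"pitch dimensions must be positive, got length={self.length}, "
                f"width={self.width}, target_depth={self.target_depth}"
            )
        adj: dict[int, frozenset[int]] = {}
        for z in range(1, N_ZONES + 1):
            r, c = _zone_rc(z)
            neigh = set()
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == dc == 0:
                        continue
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < N_ZONE_ROWS and 0 <= cc < N_ZONE_COLS:
                        neigh.add(rr * N_ZONE_COLS + cc + 1)
            adj[z] = frozenset(neigh)
        object.__setattr__(self, "adjacency", adj)

    # -- geometry queries ---------------------------------------------------

    @property
    def target_x(self) -> float:
        """x coordinate of the target-zone boundary line."""
        return self.length

    @property
    def target_point(self) -> tuple[float, float]:
        """Centre of the target-zone boundary line."""
        return (self.length, self.width / 2.0)

    def zone_bounds(self, zone: int) -> tuple[float, float, float, float]:
        """Half-open bounds ``(x0, x1, y0, y1)`` of a sub-area."""
        r, c = _zone_rc(zone)
        dx = self.length / N_ZONE_COLS
        dy = self.width / N_ZONE_ROWS
        return (c * dx, (c + 1) * dx, r * dy, (r + 1) * dy)

    def zone_centroid(self, zone: int) -> tuple[float, float]:
        x0, x1, y0, y1 = self.zone_bounds(zone)
        return ((x0 + x1) / 2.0, (y0 + y1) / 2.0)

    def zone_of(self, x: float, y: float) -> int | None:
        """Sub-area containing (x, y), or None outside the playing area."""
        if not (0 <= x <= self.length and 0 <= y <= self.width):
            return None
        c = min(int(x / (self.length / N_ZONE_COLS)), N_ZONE_COLS - 1)
        r = min(int(y / (self.width / N_ZONE_ROWS)), N_ZONE_ROWS - 1)
        return r * N_ZONE_COLS + c + 1

    def neighbors(self, zone: int) -> frozenset[int]:
        return self.adjacency[zone]

    def permitted_rect(self, zone: int, condition: str) -> tuple[float, float, float, float]:
        """Bounding rectangle a non-carrier anchored to ``zone`` may occupy.

        Under 8-neighbour adjacency the union of a zone and its neighbours is
        itself a rectangle, so every constraint regime yields one rectangle:
        restricted -> the home zone; semi -> home plus adjacent zones;
        free -> the whole playing area.
        """
        if condition == "free":
            return (0.0, self.length, 0.0, self.width)
        r, c = _zone_rc(zone)
        if condition == "restricted":
            rows, cols = (r, r), (c, c)
        elif condition == "semi":
            rows = (max(r - 1, 0), min(r + 1, N_ZONE_ROWS - 1))
            cols = (max(c - 1, 0), min(c + 1, N_ZONE_COLS - 1))
        else:
            raise InvalidGeometryError(f"unknown condition {condition!r}")
        dx = self.length / N_ZONE_COLS
        dy = self.width / N_ZONE_ROWS
        return (cols[0] * dx, (cols[1] + 1) * dx, rows[0] * dy, (rows[1] + 1) * dy)

    def distance_to_target_line(self, x: float | np.ndarray) -> float | np.ndarray:
        """Signed longitudinal distance from the target-zone boundary line.

        Positive before the line (outside the target zone), negative past it.
        """
        return self.target_x - np.asarray(x) if isinstance(x, np.ndarray) else self.target_x - x


def build_pitch(length: float = 37.5, width: float = 60.0, target_depth: float = 5.0) -> Pitch:
    """Construct a :class:`Pitch`; raises :class:`InvalidGeometryError` on
    non-positive dimensions."""
    return Pitch(length=length, width=width, target_depth=target_depth)
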