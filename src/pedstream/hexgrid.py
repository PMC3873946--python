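"""Hexagonal lattice geometry for the cellular automaton.

The walkable world is a triangular lattice of cell centers with spacing
``lattice_constant`` (default 0.53 m, one body diameter), each cell being the
hexagonal Voronoi region of its center.  Compared to a square grid the
hexagonal one offers two additional natural directions of movement, which
reduces lattice artifacts in the paths agents take.

Coordinates: axial integer pairs ``(q, r)`` with Cartesian centers

    x = x_min + a * (q + r / 2)
    y = y_min + a * (sqrt(3) / 2) * r

so the six lattice directions sit at angles 0, 60, ..., 300 degrees.  The
lattice is anchored at the lower-left corner of the extent; only cells whose
center lies inside the extent exist, and the extent boundary behaves like an
obstacle (there is no world outside the grid).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterable, Sequence

import numpy as np
import shapely
from scipy.spatial import cKDTree
from shapely.geometry import Polygon

__all__ = [
    "AXIAL_DIRECTIONS",
    "CellState",
    "HexGrid",
    "build_grid",
    "cell_of_point",
    "neighbors",
]

#: Fixed axial direction order (counterclockwise from east); all neighbor
#: enumeration and deterministic tie-breaking follow this order.
AXIAL_DIRECTIONS: tuple[tuple[int, int], ...] = (
    (1, 0),
    (0, 1),
    (-1, 1),
    (-1, 0),
    (0, -1),
    (1, -1),
)

_EPS = 1e-9


class CellState(IntEnum):
    """State of one lattice cell at one instant."""

    EMPTY = 0
    PERSON = 1
    OBSTACLE = 2
    TARGET = 3
    SOURCE = 4


def _as_polygon(obj) -> Polygon:
    if isinstance(obj, Polygon):
        return obj
    return Polygon(obj)


@dataclass
class HexGrid:
    """Indexed hexagonal lattice covering a rectangular extent.

    Attributes
    ----------
    extent
        ``(x_min, y_min, x_max, y_max)`` in meters.
    lattice_constant
        Center-to-center spacing of adjacent cells, meters.
    axial
        ``(n, 2)`` integer array of axial ``(q, r)`` indices.
    centers
        ``(n, 2)`` float array of Cartesian cell centers, meters.
    state
        ``(n,)`` array of :class:`CellState` values.
    """

    extent: tuple[float, float, float, float]
    lattice_constant: float
    axial: np.ndarray
    centers: np.ndarray
    state: np.ndarray
    _index_of_axial: dict[tuple[int, int], int] = field(repr=False, default_factory=dict)
    _neighbor_table: np.ndarray | None = field(repr=False, default=None)
    _tree: cKDTree | None = field(repr=False, default=None)

    # -- basic introspection -------------------------------------------------

    @property
    def n_cells(self) -> int:
        return len(self.centers)

    @property
    def cell_area(self) -> float:
        """Area of one (unclipped) hexagonal cell, m^2."""
        return math.sqrt(3.0) / 2.0 * self.lattice_constant**2

    def index_of_axial(self, q: int, r: int) -> int:
        return self._index_of_axial[(q, r)]

    def walkable(self) -> np.ndarray:
        """Boolean mask of cells that are not obstacles."""
        return self.state != CellState.OBSTACLE

    # -- adjacency -----------------------------------------------------------

    @property
    def neighbor_table(self) -> np.ndarray:
        """``(n, 6)`` neighbor indices in fixed direction order, ``-1`` if absent."""
        if self._neighbor_table is None:
            table = np.full((self.n_cells, 6), -1, dtype=np.int64)
            for i, (q, r) in enumerate(self.axial):
                for d, (dq, dr) in enumerate(AXIAL_DIRECTIONS):
                    j = self._index_of_axial.get((q + dq, r + dr))
                    if j is not None:
                        table[i, d] = j
            self._neighbor_table = table
        return self._neighbor_table

    def neighbors(self, cell: int) -> list[int]:
        """Lattice-adjacent cells inside the extent, in fixed direction order."""
        if not 0 <= cell < self.n_cells:
            raise KeyError(f"unknown cell index {cell}")
        row = self.neighbor_table[cell]
        return [int(j) for j in row if j >= 0]

    # -- geometry ------------------------------------------------------------

    def cell_polygon(self, cell: int) -> Polygon:
        """Hexagonal Voronoi region of a cell center (unclipped)."""
        cx, cy = self.centers[cell]
        rad = self.lattice_constant / math.sqrt(3.0)
        angles = np.deg2rad(30.0 + 60.0 * np.arange(6))
        return Polygon(np.column_stack([cx + rad * np.cos(angles), cy + rad * np.sin(angles)]))

    def cell_of_point(self, x: float, y: float) -> int:
        """Cell whose center is nearest to ``(x, y)``; ties go to the smaller index.

        Raises ``ValueError`` for points outside the extent.
        """
        x_min, y_min, x_max, y_max = self.extent
        if not (x_min - _EPS <= x <= x_max + _EPS and y_min - _EPS <= y <= y_max + _EPS):
            raise ValueError(f"point ({x}, {y}) lies outside the extent {self.extent}")
        if self._tree is None:
            self._tree = cKDTree(self.centers)
        k = min(3, self.n_cells)
        dist, idx = self._tree.query([x, y], k=k)
        dist = np.atleast_1d(dist)
        idx = np.atleast_1d(idx)
        near = idx[dist <= dist[0] + _EPS]
        return int(near.min())

    def cells_of_points(self, xy: np.ndarray) -> np.ndarray:
        """Vectorized nearest-center lookup (no tie canonicalization)."""
        if self._tree is None:
            self._tree = cKDTree(self.centers)
        _, idx = self._tree.query(np.asarray(xy, dtype=float))
        return np.asarray(idx, dtype=np.int64)

    def cells_in_polygon(self, poly) -> np.ndarray:
        """Indices of cells whose center is covered by ``poly`` (boundary inclusive)."""
        poly = _as_polygon(poly)
        mask = shapely.intersects_xy(poly, self.centers[:, 0], self.centers[:, 1])
        return np.flatnonzero(mask)


def build_grid(
    extent: Sequence[float],
    lattice_constant: float = 0.53,
    obstacles: Iterable = (),
) -> HexGrid:
    """Build the hexagonal grid covering ``extent`` and rasterize obstacles.

    Parameters
    ----------
    extent
        ``(x_min, y_min, x_max, y_max)`` in meters; must be non-degenerate.
    lattice_constant
        Adjacent cell-center spacing in meters (default 0.53, one body
        diameter, so a single move covers one body diameter of travel).
    obstacles
        Polygons (shapely or coordinate sequences); a cell becomes OBSTACLE
        iff its center lies strictly inside one of them.
    """
    x_min, y_min, x_max, y_max = map(float, extent)
    if not x_max > x_min:
        raise ValueError(f"extent is degenerate: x_max ({x_max}) must exceed x_min ({x_min})")
    if not y_max > y_min:
        raise ValueError(f"extent is degenerate: y_max ({y_max}) must exceed y_min ({y_min})")
    if not lattice_constant > 0:
        raise ValueError(f"lattice_constant must be positive, got {lattice_constant}")

    a = float(lattice_constant)
    row_h = a * math.sqrt(3.0) / 2.0
    r_max = int(math.floor((y_max - y_min) / row_h + _EPS))

    axial: list[tuple[int, int]] = []
    for r in range(r_max + 1):
        # x = x_min + a*(q + r/2) within [x_min, x_max]
        q_lo = int(math.ceil(-r / 2.0 - _EPS))
        q_hi = int(math.floor((x_max - x_min) / a - r / 2.0 + _EPS))
        axial.extend((q, r) for q in range(q_lo, q_hi + 1))

    axial_arr = np.array(axial, dtype=np.int64).reshape(-1, 2)
    centers = np.column_stack(
        [
            x_min + a * (axial_arr[:, 0] + axial_arr[:, 1] / 2.0),
            y_min + row_h * axial_arr[:, 1],
        ]
    )
    state = np.full(len(axial_arr), CellState.EMPTY, dtype=np.uint8)

    polys = [_as_polygon(p) for p in obstacles]
    if polys:
        blocked = np.zeros(len(centers), dtype=bool)
        for poly in polys:
            blocked |= shapely.contains_xy(poly, centers[:, 0], centers[:, 1])
        state[blocked] = CellState.OBSTACLE

    grid = HexGrid(
        extent=(x_min, y_min, x_max, y_max),
        lattice_constant=a,
        axial=axial_arr,
        centers=centers,
        state=state,
    )
    grid._index_of_axial = {(int(q), int(r)): i for i, (q, r) in enumerate(axial_arr)}
    return grid


def neighbors(grid: HexGrid, cell: int) -> list[int]:
    """Functional alias for :meth:`HexGrid.neighbors`."""
    return grid.neighbors(cell)


def cell_of_point(grid: HexGrid, x: float, y: float) -> int:
    """Functional alias for :meth:`HexGrid.cell_of_point`."""
    return grid.cell_of_point(x, y)
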