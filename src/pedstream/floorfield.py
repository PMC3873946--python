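"""Target floor field: arrival time of a wavefront expanding from the target.

The long-range attraction of a target is encoded as the arrival time of a
wave front traveling at constant speed (normalized to 1 m/s) from the target
cells through obstacle-free space, so field values are shortest-path
distances in meters along the hex adjacency graph.  Descending the field
greedily takes an agent along a shortest obstacle-free path to its target.

The wavefront expansion is a monotone multi-source shortest-path computation
on the lattice graph with all edge weights equal to the lattice constant.
Static obstacles only; the field is recomputed when topology changes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from pedstream.hexgrid import CellState, HexGrid

__all__ = ["FloorField", "compute_floor_field", "steepest_descent_neighbor"]


@dataclass
class FloorField:
    """Per-cell wavefront arrival values for one target.

    ``values[i]`` is the graph shortest-path distance (m) from cell ``i`` to
    the nearest target cell; ``+inf`` marks cells that are unreachable
    (including obstacle cells, which the wave never enters).
    """

    target_id: str
    values: np.ndarray

    def reachable(self, cell: int) -> bool:
        return bool(np.isfinite(self.values[cell]))


def _walkable_graph(grid: HexGrid) -> csr_matrix:
    table = grid.neighbor_table
    walk = grid.walkable()
    src, dirs = np.nonzero(table >= 0)
    dst = table[src, dirs]
    keep = walk[src] & walk[dst]
    src, dst = src[keep], dst[keep]
    w = np.full(len(src), grid.lattice_constant)
    n = grid.n_cells
    return csr_matrix((w, (src, dst)), shape=(n, n))


def compute_floor_field(grid: HexGrid, target_cells, target_id: str = "target") -> FloorField:
    """Expand the wavefront from ``target_cells`` over the walkable graph.

    Raises ``ValueError`` if no target cell is walkable.  Cells disconnected
    from every target are flagged unreachable (``+inf``), not an error.
    """
    target_cells = np.asarray(list(target_cells), dtype=np.int64)
    if target_cells.size == 0:
        raise ValueError("target_cells must be nonempty")
    walk = grid.walkable()
    sources = target_cells[walk[target_cells]]
    if sources.size == 0:
        raise ValueError("all target cells lie inside obstacles; the target is unreachable")

    graph = _walkable_graph(grid)
    values = dijkstra(graph, directed=False, indices=sources, min_only=True)
    values[~walk] = np.inf
    return FloorField(target_id=target_id, values=np.asarray(values))


def steepest_descent_neighbor(
    field: FloorField,
    grid: HexGrid,
    cell: int,
    occupancy: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> int | None:
    """Free neighbor with the lowest floor-field value, or ``None``.

    A neighbor is available if its cell state is EMPTY or TARGET and it is
    not occupied (per ``occupancy``, an optional boolean mask of occupied
    cells).  Returns ``None`` when no available neighbor strictly improves on
    the current cell's value.  Equal-valued minimizers are resolved by the
    fixed axial direction order, or uniformly at random when ``rng`` is given.
    """
    here = field.values[cell]
    best_val = here
    best: list[int] = []
    for j in grid.neighbors(cell):
        s = grid.state[j]
        if s != CellState.EMPTY and s != CellState.TARGET and s != CellState.SOURCE:
            continue
        if occupancy is not None and occupancy[j]:
            continue
        v = field.values[j]
        if v < best_val - 1e-12:
            best_val = v
            best = [j]
        elif best and abs(v - best_val) <= 1e-12:
            best.append(j)
    if not best:
        return None
    if rng is None or len(best) == 1:
        return best[0]
    return int(best[int(rng.integers(len(best)))])
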