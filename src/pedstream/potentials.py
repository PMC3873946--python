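"""Repulsive potentials and their aggregation into the overall potential.

Borrowing from electrostatics, pedestrians and obstacles carry repulsive
potentials while the target attracts through the floor field; the scalar
contributions are summed into one overall potential whose steepest descent
drives every step.  Both repulsion terms use an exponentially decaying
radially symmetric profile with a hard cutoff,

    V(r) = A * exp(-r / lambda)   for r < r_cut,   else 0,

which is almost zero a few cells away from a person, monotone, and has two
interpretable parameters (contact amplitude ``A`` and decay length
``lambda``) per term — both calibration targets, not measured constants.
Distances are Euclidean between cell centers so the profiles are truly
radially symmetric rather than lattice-metric dependent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial import cKDTree

from pedstream.floorfield import FloorField
from pedstream.hexgrid import CellState, HexGrid

__all__ = [
    "PotentialParams",
    "agent_potential",
    "obstacle_potential",
    "total_potential",
    "ObstacleField",
]

_DEFAULT_A = 0.53  # lattice constant used for parameter fallbacks, m


@dataclass(frozen=True)
class PotentialParams:
    """Amplitudes, decay lengths and cutoffs of the repulsion terms.

    Defaults let the simulator run uncalibrated: the agent amplitude is ten
    times the floor-field weight so a contact never pays off against path
    gain, the agent decay length is half a cell, the agent cutoff "a few
    cells" (three lattice constants), and the obstacle cutoff 2.0 m — the
    observed influence range of a wall.
    """

    agent_amplitude: float = 10.0
    agent_range: float = 0.5 * _DEFAULT_A
    agent_cutoff: float = 3.0 * _DEFAULT_A
    obstacle_amplitude: float = 5.0
    obstacle_range: float = 0.5
    obstacle_cutoff: float = 2.0
    floorfield_weight: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "agent_amplitude",
            "agent_range",
            "agent_cutoff",
            "obstacle_amplitude",
            "obstacle_range",
            "obstacle_cutoff",
            "floorfield_weight",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.agent_cutoff < self.agent_range:
            raise ValueError("agent_cutoff must be >= agent_range")
        if self.obstacle_cutoff < self.obstacle_range:
            raise ValueError("obstacle_cutoff must be >= obstacle_range")

    def with_(self, **kwargs) -> "PotentialParams":
        return replace(self, **kwargs)


def _exp_repulsion(r, amplitude: float, decay: float, cutoff: float):
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("distance must be nonnegative")
    out = np.where(r < cutoff, amplitude * np.exp(-r / decay), 0.0)
    return out if out.ndim else float(out)


def agent_potential(r, params: PotentialParams):
    """Repulsion exerted by one pedestrian at Euclidean distance ``r`` (m)."""
    return _exp_repulsion(r, params.agent_amplitude, params.agent_range, params.agent_cutoff)


def obstacle_potential(d, params: PotentialParams):
    """Repulsion exerted by one obstacle cell at Euclidean distance ``d`` (m)."""
    return _exp_repulsion(d, params.obstacle_amplitude, params.obstacle_range, params.obstacle_cutoff)


class ObstacleField:
    """Precomputed summed obstacle repulsion per cell (static topology)."""

    def __init__(self, grid: HexGrid, params: PotentialParams):
        self.values = np.zeros(grid.n_cells)
        obstacle_idx = np.flatnonzero(grid.state == CellState.OBSTACLE)
        if obstacle_idx.size == 0:
            return
        tree = cKDTree(grid.centers[obstacle_idx])
        pairs = tree.query_ball_point(grid.centers, r=params.obstacle_cutoff)
        for i, near in enumerate(pairs):
            if near:
                d = np.linalg.norm(grid.centers[obstacle_idx[near]] - grid.centers[i], axis=1)
                self.values[i] = obstacle_potential(d, params).sum()


def total_potential(
    cell: int,
    agent_positions: np.ndarray,
    grid: HexGrid,
    field: FloorField,
    params: PotentialParams,
    obstacle_field: ObstacleField | None = None,
) -> float:
    """Overall potential at a cell: floor field + agent + obstacle repulsion.

    ``agent_positions`` holds the (x, y) centers of the *other* agents — the
    stepping agent's own contribution must already be excluded by the caller.
    Unreachable cells get ``+inf`` so they are never selected.
    """
    if not field.reachable(cell):
        return math.inf
    value = params.floorfield_weight * float(field.values[cell])
    agent_positions = np.asarray(agent_positions, dtype=float).reshape(-1, 2)
    if len(agent_positions):
        d = np.linalg.norm(agent_positions - grid.centers[cell], axis=1)
        value += float(np.sum(agent_potential(d, params)))
    if obstacle_field is None:
        obstacle_field = ObstacleField(grid, params)
    value += float(obstacle_field.values[cell])
    return value
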