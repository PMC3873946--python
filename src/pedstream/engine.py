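"""Agents, sources, targets and the velocity-proportional sequential update.

Each virtual pedestrian carries an individual free-flow speed drawn from a
truncated normal profile.  Time advances in fixed global steps; every step
each agent accrues distance credit ``v * dt`` and becomes *due* once the
credit reaches one lattice constant, so faster agents are selected for a
move more often and on average realize exactly their prescribed speed while
the path is free.  Due agents act one at a time in the order of their
lifetime in the simulation (oldest first by default), which makes collisions
structurally impossible: each mover sees the already-updated occupancy.  A
move goes to the empty neighbor cell with the steepest descent of the
overall potential; an agent stays put when no neighbor strictly improves on
its current cell, which is what produces slowing down and evasion in dense
crowds.

The model is microscopic, discrete and deterministic with stochastic
aspects, rule-based but potential-driven.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm
from shapely.geometry import Polygon

from pedstream._rng import substream
from pedstream.floorfield import FloorField, compute_floor_field
from pedstream.hexgrid import CellState, HexGrid, build_grid
from pedstream.potentials import ObstacleField, PotentialParams, agent_potential
from pedstream.trajectories import TrajectoryDataset

__all__ = [
    "Agent",
    "Schedule",
    "Scenario",
    "SourceSpec",
    "TargetSpec",
    "SimulationResult",
    "SimulationState",
    "VelocityProfile",
    "run_simulation",
    "sample_free_flow_speed",
    "select_due_agents",
    "spawn_agents",
    "step_agent",
]


@dataclass(frozen=True)
class VelocityProfile:
    """Truncated-normal free-flow speed distribution, m/s.

    ``lower``/``upper`` double as the outlier bounds used during estimation
    (defaults 0.1 and 4.0 m/s — below the first, dawdlers and loiterers are
    indistinguishable; above the second, runners).
    """

    mean: float
    sd: float
    lower: float = 0.1
    upper: float = 4.0
    n_samples: int | None = None
    outliers_removed: int = 0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError(f"sd must be nonnegative, got {self.sd}")
        if not 0 < self.lower < self.upper:
            raise ValueError(f"bounds must satisfy 0 < lower < upper, got ({self.lower}, {self.upper})")


def sample_free_flow_speed(profile: VelocityProfile, rng: np.random.Generator, size: int | None = None):
    """Draw free-flow speeds: normal(mean, sd) redrawn until inside the bounds.

    Deterministic under a fixed generator state.  Raises ``ValueError`` when
    the bounds exclude at least 99.9% of the distribution's mass (degenerate
    profile) — rejection would practically never terminate and the profile
    no longer resembles its normal fit.
    """
    if profile.sd == 0.0:
        if not profile.lower <= profile.mean <= profile.upper:
            raise ValueError("degenerate profile: zero sd with mean outside the bounds")
        return float(profile.mean) if size is None else np.full(size, float(profile.mean))
    mass = norm.cdf(profile.upper, profile.mean, profile.sd) - norm.cdf(profile.lower, profile.mean, profile.sd)
    if mass < 1e-3:
        raise ValueError(
            f"degenerate profile: bounds ({profile.lower}, {profile.upper}) retain only "
            f"{mass:.2e} of the normal({profile.mean}, {profile.sd}) mass"
        )
    n = 1 if size is None else int(size)
    out = np.empty(n)
    todo = np.arange(n)
    while todo.size:
        draws = rng.normal(profile.mean, profile.sd, size=todo.size)
        ok = (draws >= profile.lower) & (draws <= profile.upper)
        out[todo[ok]] = draws[ok]
        todo = todo[~ok]
    return float(out[0]) if size is None else out


@dataclass(frozen=True)
class Schedule:
    """Arrival events ``(time s, count)`` for one source."""

    events: tuple[tuple[float, int], ...]

    def __post_init__(self) -> None:
        for t, c in self.events:
            if t < 0:
                raise ValueError(f"schedule event time must be >= 0, got {t}")
            if c < 1:
                raise ValueError(f"schedule event count must be >= 1, got {c}")

    @property
    def total(self) -> int:
        return sum(c for _, c in self.events)


@dataclass(frozen=True)
class SourceSpec:
    id: str
    region: Polygon
    schedule: Schedule


@dataclass(frozen=True)
class TargetSpec:
    id: str
    region: Polygon


@dataclass
class Agent:
    """One virtual pedestrian."""

    id: int
    free_flow_speed: float
    current_cell: int
    target_id: str
    spawn_time: float
    source_id: str = ""
    move_credit: float = 0.0
    moves: int = 0
    exit_time: float | None = None


@dataclass
class Scenario:
    """Topology, sources/targets, schedules, distributions and model parameters."""

    extent: tuple[float, float, float, float]
    sources: list[SourceSpec]
    targets: list[TargetSpec]
    source_target_matrix: dict[str, dict[str, float]]
    velocity_profile: VelocityProfile
    duration: float
    obstacles: list = dc_field(default_factory=list)
    lattice_constant: float = 0.53
    potential_params: PotentialParams = dc_field(default_factory=PotentialParams)
    time_step: float = 0.1
    update_order: str = "oldest_first"
    recycle: dict[str, str] = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError(f"duration must be positive, got {self.duration}")
        if self.time_step <= 0:
            raise ValueError(f"time_step must be positive, got {self.time_step}")
        if self.update_order not in ("oldest_first", "newest_first"):
            raise ValueError(f"update_order must be oldest_first or newest_first, got {self.update_order!r}")
        target_ids = {t.id for t in self.targets}
        for src in self.sources:
            row = self.source_target_matrix.get(src.id)
            if row is None:
                raise ValueError(f"source_target_matrix is missing a row for source {src.id!r}")
            if any(p < 0 for p in row.values()):
                raise ValueError(f"source_target_matrix row {src.id!r} has negative entries")
            if abs(sum(row.values()) - 1.0) > 1e-9:
                raise ValueError(
                    f"source_target_matrix row {src.id!r} sums to {sum(row.values()):.6g}, expected 1"
                )
            unknown = set(row) - target_ids
            if unknown:
                raise ValueError(f"source_target_matrix row {src.id!r} references unknown targets {sorted(unknown)}")
        for tid, sid in self.recycle.items():
            if tid not in target_ids:
                raise ValueError(f"recycle references unknown target {tid!r}")
            if sid not in {s.id for s in self.sources}:
                raise ValueError(f"recycle references unknown source {sid!r}")


class SimulationState:
    """Mutable world state shared by spawn/select/step during one run."""

    def __init__(self, scenario: Scenario):
        self.scenario = scenario
        self.grid: HexGrid = build_grid(scenario.extent, scenario.lattice_constant, scenario.obstacles)
        grid = self.grid

        self.source_cells: dict[str, np.ndarray] = {}
        for src in scenario.sources:
            cells = grid.cells_in_polygon(src.region)
            cells = cells[grid.state[cells] != CellState.OBSTACLE]
            if cells.size == 0:
                raise ValueError(f"source {src.id!r} region contains no walkable cells")
            grid.state[cells] = CellState.SOURCE
            self.source_cells[src.id] = cells
        self.target_cells: dict[str, np.ndarray] = {}
        for tgt in scenario.targets:
            cells = grid.cells_in_polygon(tgt.region)
            cells = cells[grid.state[cells] != CellState.OBSTACLE]
            if cells.size == 0:
                raise ValueError(f"target {tgt.id!r} region contains no walkable cells")
            grid.state[cells] = CellState.TARGET
            self.target_cells[tgt.id] = cells
        self._target_cell_sets = {tid: set(map(int, c)) for tid, c in self.target_cells.items()}

        self.fields: dict[str, FloorField] = {
            tid: compute_floor_field(grid, cells, tid) for tid, cells in self.target_cells.items()
        }
        # reachability check at load time, not at runtime
        for src in scenario.sources:
            for tid, p in scenario.source_target_matrix[src.id].items():
                if p <= 0:
                    continue
                vals = self.fields[tid].values[self.source_cells[src.id]]
                if not np.any(np.isfinite(vals)):
                    raise ValueError(f"target {tid!r} is unreachable from source {src.id!r}")

        self.obstacle_field = ObstacleField(grid, scenario.potential_params)
        self.occupied = np.zeros(grid.n_cells, dtype=bool)
        self.agents: dict[int, Agent] = {}
        self.queued_arrivals: list[tuple[str, str | None, float | None]] = []  # (source, target, speed)
        self.queue_warnings = 0
        self.next_id = 0
        self.time = 0.0

    # -- occupancy helpers ---------------------------------------------------

    def place(self, agent: Agent, cell: int) -> None:
        self.occupied[cell] = True
        agent.current_cell = cell
        self.agents[agent.id] = agent

    def vacate(self, agent: Agent) -> None:
        self.occupied[agent.current_cell] = False
        del self.agents[agent.id]

    def other_agent_positions(self, agent_id: int) -> np.ndarray:
        cells = [a.current_cell for a in self.agents.values() if a.id != agent_id]
        return self.grid.centers[cells] if cells else np.empty((0, 2))

    def is_free(self, cell: int) -> bool:
        s = self.grid.state[cell]
        return (s == CellState.EMPTY or s == CellState.TARGET or s == CellState.SOURCE) and not self.occupied[cell]


def spawn_agents(scenario: Scenario, t: float, state: SimulationState, rng: np.random.Generator) -> list[Agent]:
    """Place due arrivals on free source cells; queue overflow for retry.

    Each arrival gets a uniformly chosen free cell of its source region, a
    target drawn from the source's probability row and a speed drawn from the
    scenario velocity profile (unless preset by a recycle event).
    """
    due = list(state.queued_arrivals)
    state.queued_arrivals = []
    for src in scenario.sources:
        for ev_t, count in src.schedule.events:
            if state.time - scenario.time_step < ev_t <= state.time or (ev_t == 0.0 and state.time == 0.0):
                due.extend((src.id, None, None) for _ in range(count))

    spawned: list[Agent] = []
    for source_id, preset_target, preset_speed in due:
        free = [int(c) for c in state.source_cells[source_id] if state.is_free(int(c))]
        if not free:
            state.queued_arrivals.append((source_id, preset_target, preset_speed))
            state.queue_warnings += 1
            continue
        cell = free[int(rng.integers(len(free)))]
        if preset_target is None:
            row = scenario.source_target_matrix[source_id]
            tids = sorted(row)
            probs = np.array([row[k] for k in tids])
            target_id = tids[int(rng.choice(len(tids), p=probs / probs.sum()))]
        else:
            target_id = preset_target
        speed = preset_speed if preset_speed is not None else sample_free_flow_speed(scenario.velocity_profile, rng)
        agent = Agent(
            id=state.next_id,
            free_flow_speed=float(speed),
            current_cell=cell,
            target_id=target_id,
            spawn_time=t,
            source_id=source_id,
        )
        state.next_id += 1
        state.place(agent, cell)
        spawned.append(agent)
    return spawned


def select_due_agents(
    agents: Sequence[Agent],
    time_step: float,
    lattice_constant: float = 0.53,
    order: str = "oldest_first",
) -> list[Agent]:
    """Accrue move credit and return agents due to move, lifetime-ordered.

    Every agent's credit grows by ``free_flow_speed * time_step``; agents
    whose credit reaches one lattice constant are due (the credit is debited
    on each attempted move, not here).  Ordering: oldest spawn time first by
    default, ties by id.
    """
    if time_step <= 0:
        raise ValueError(f"time_step must be positive, got {time_step}")
    due = []
    for agent in agents:
        agent.move_credit += agent.free_flow_speed * time_step
        if agent.move_credit >= lattice_constant:
            due.append(agent)
    reverse = order == "newest_first"
    return sorted(due, key=lambda a: (-a.spawn_time if reverse else a.spawn_time, a.id))


def _candidate_potentials(agent: Agent, cells: np.ndarray, state: SimulationState) -> np.ndarray:
    """Overall potential at candidate cells, excluding the agent's own term."""
    params = state.scenario.potential_params
    ff = state.fields[agent.target_id].values[cells]
    vals = params.floorfield_weight * ff + state.obstacle_field.values[cells]
    others = state.other_agent_positions(agent.id)
    if len(others):
        diff = others[None, :, :] - state.grid.centers[cells][:, None, :]
        d = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
        contrib = np.where(d < params.agent_cutoff, params.agent_amplitude * np.exp(-d / params.agent_range), 0.0)
        vals = vals + contrib.sum(axis=1)
    return vals


def step_agent(agent: Agent, state: SimulationState, rng: np.random.Generator) -> int | None:
    """Attempt one move: steepest descent of the overall potential.

    Returns the new cell index, or ``None`` if the agent stays (no free
    neighbor strictly improves on the current cell).  Ties among minimizing
    neighbors are broken uniformly at random.  Stepping onto a cell of the
    agent's own target region absorbs the agent.
    """
    grid = state.grid
    here = agent.current_cell
    free_neighbors = [j for j in grid.neighbors(here) if state.is_free(j)]
    cells = np.array([here] + free_neighbors, dtype=np.int64)
    vals = _candidate_potentials(agent, cells, state)
    best = np.min(vals[1:]) if len(cells) > 1 else np.inf
    if not best < vals[0] - 1e-12:
        return None
    winners = [cells[i] for i in range(1, len(cells)) if vals[i] <= best + 1e-12]
    new_cell = int(winners[0] if len(winners) == 1 else winners[int(rng.integers(len(winners)))])

    state.occupied[here] = False
    state.occupied[new_cell] = True
    agent.current_cell = new_cell
    agent.moves += 1
    return new_cell


@dataclass
class SimulationResult:
    """Simulated trajectories plus the spawn/exit event log."""

    trajectories: TrajectoryDataset
    events: pd.DataFrame  # ped_id, spawn_t, source, target, exit_t, moves
    queue_warnings: int
    seed: int

    def realized_mean_speed(self) -> float:
        """Distance moved per unit active time, pooled over all agents."""
        ev = self.events
        if len(ev) == 0:
            return 0.0
        t_end = float(self.trajectories.df["t"].max()) if len(self.trajectories) else 0.0
        active = (ev["exit_t"].fillna(t_end) - ev["spawn_t"]).to_numpy(dtype=float)
        total_time = float(active.sum())
        if total_time == 0:
            return 0.0
        return float(ev["moves"].sum() * self._lattice_constant / total_time)

    _lattice_constant: float = 0.53


def run_simulation(scenario: Scenario, seed: int) -> SimulationResult:
    """Run the sequential-update loop for ``scenario.duration`` seconds.

    Per global step: spawn due arrivals, select due agents (credit accrual),
    then step each due agent in lifetime order; every agent's cell-center
    position is recorded at every step.  Fully reproducible from
    ``(scenario, seed)``.
    """
    state = SimulationState(scenario)
    rng_spawn = substream(seed, "spawn")
    rng_ties = substream(seed, "ties")
    dt = scenario.time_step
    a_lat = scenario.lattice_constant
    n_steps = int(round(scenario.duration / dt))

    rec_id: list[int] = []
    rec_t: list[float] = []
    rec_x: list[float] = []
    rec_y: list[float] = []
    event_rows: dict[int, dict] = {}

    for k in range(n_steps + 1):
        t = k * dt
        state.time = t
        for agent in spawn_agents(scenario, t, state, rng_spawn):
            event_rows[agent.id] = {
                "ped_id": agent.id,
                "spawn_t": t,
                "source": agent.source_id,
                "target": agent.target_id,
                "speed": agent.free_flow_speed,
                "exit_t": np.nan,
                "moves": 0,
            }

        if k > 0:
            due = select_due_agents(list(state.agents.values()), dt, a_lat, scenario.update_order)
            for agent in due:
                while agent.move_credit >= a_lat and agent.id in state.agents:
                    agent.move_credit -= a_lat
                    new_cell = step_agent(agent, state, rng_ties)
                    if new_cell is None:
                        break
                    if new_cell in state._target_cell_sets[agent.target_id]:
                        agent.exit_time = t
                        cx, cy = state.grid.centers[new_cell]
                        rec_id.append(agent.id)
                        rec_t.append(t)
                        rec_x.append(float(cx))
                        rec_y.append(float(cy))
                        state.vacate(agent)
                        row = event_rows[agent.id]
                        row["exit_t"] = t
                        row["moves"] = agent.moves
                        recycle_src = scenario.recycle.get(agent.target_id)
                        if recycle_src is not None:
                            state.queued_arrivals.append(
                                (recycle_src, agent.target_id, agent.free_flow_speed)
                            )

        for agent in state.agents.values():
            cx, cy = state.grid.centers[agent.current_cell]
            rec_id.append(agent.id)
            rec_t.append(t)
            rec_x.append(float(cx))
            rec_y.append(float(cy))

    for agent in state.agents.values():
        event_rows[agent.id]["moves"] = agent.moves

    df = pd.DataFrame({"ped_id": rec_id, "t": rec_t, "x": rec_x, "y": rec_y})
    events = pd.DataFrame(
        event_rows.values(),
        columns=["ped_id", "spawn_t", "source", "target", "speed", "exit_t", "moves"],
    )
    result = SimulationResult(
        trajectories=TrajectoryDataset(df, sampling_interval=dt),
        events=events,
        queue_warnings=state.queue_warnings,
        seed=seed,
    )
    result._lattice_constant = a_lat
    return result
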