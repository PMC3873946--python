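"""Scenario configuration files, trajectory tables and synthetic fixtures.

Configs are human-readable YAML mappings (JSON is valid YAML and accepted
interchangeably); serialization is canonical — sorted keys, plain floats —
so configs diff cleanly and round-trip losslessly.  Trajectory tables are
delimited text with header ``ped_id,t,x,y`` (seconds, meters; Cartesian
frame, origin at the extent's lower-left corner, y up).

The fixture generator produces trajectory datasets with *known* ground truth
(per-agent speeds, targets, arrival times), standing in for field video data
so every estimator can be tested against the truth that generated its input.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import Point, Polygon

from pedstream._rng import substream
from pedstream.engine import (
    Scenario,
    Schedule,
    SourceSpec,
    TargetSpec,
    VelocityProfile,
    run_simulation,
    sample_free_flow_speed,
)
from pedstream.potentials import PotentialParams
from pedstream.trajectories import TrajectoryDataset

__all__ = [
    "FixtureSpec",
    "generate_fixture",
    "load_scenario",
    "read_trajectories",
    "save_scenario",
    "scenario_from_dict",
    "scenario_to_dict",
    "write_trajectories",
    "config_hash",
]


# ---------------------------------------------------------------------------
# scenario configs
# ---------------------------------------------------------------------------


def _poly_to_coords(poly: Polygon) -> list[list[float]]:
    xy = list(poly.exterior.coords)
    if len(xy) > 1 and xy[0] == xy[-1]:
        xy = xy[:-1]
    return [[float(x), float(y)] for x, y in xy]


def _coords_to_poly(coords, where: str) -> Polygon:
    try:
        poly = Polygon(coords)
    except Exception as exc:
        raise ValueError(f"{where}: invalid polygon coordinates ({exc})")
    if poly.area <= 0:
        raise ValueError(f"{where}: polygon has zero area")
    return poly


def scenario_to_dict(scenario: Scenario) -> dict:
    p = scenario.potential_params
    v = scenario.velocity_profile
    return {
        "extent": [float(c) for c in scenario.extent],
        "lattice_constant": float(scenario.lattice_constant),
        "duration": float(scenario.duration),
        "time_step": float(scenario.time_step),
        "update_order": scenario.update_order,
        "obstacles": [_poly_to_coords(Polygon(o) if not isinstance(o, Polygon) else o) for o in scenario.obstacles],
        "sources": [
            {
                "id": s.id,
                "region": _poly_to_coords(s.region),
                "schedule": [[float(t), int(c)] for t, c in s.schedule.events],
            }
            for s in scenario.sources
        ],
        "targets": [{"id": t.id, "region": _poly_to_coords(t.region)} for t in scenario.targets],
        "source_target_matrix": {
            sid: {tid: float(p_) for tid, p_ in sorted(row.items())}
            for sid, row in sorted(scenario.source_target_matrix.items())
        },
        "velocity_profile": {
            "mean": float(v.mean),
            "sd": float(v.sd),
            "lower": float(v.lower),
            "upper": float(v.upper),
        },
        "potential_params": {
            "agent_amplitude": float(p.agent_amplitude),
            "agent_range": float(p.agent_range),
            "agent_cutoff": float(p.agent_cutoff),
            "obstacle_amplitude": float(p.obstacle_amplitude),
            "obstacle_range": float(p.obstacle_range),
            "obstacle_cutoff": float(p.obstacle_cutoff),
            "floorfield_weight": float(p.floorfield_weight),
        },
        "recycle": dict(sorted(scenario.recycle.items())),
    }


def _require(doc: dict, key: str, where: str = "scenario"):
    if key not in doc:
        raise ValueError(f"{where}: missing required field {key!r}")
    return doc[key]


def scenario_from_dict(doc: dict) -> Scenario:
    if not isinstance(doc, dict):
        raise ValueError("scenario config must be a mapping")
    extent = _require(doc, "extent")
    if not (isinstance(extent, (list, tuple)) and len(extent) == 4):
        raise ValueError("extent: expected [x_min, y_min, x_max, y_max]")

    sources = []
    for i, s in enumerate(_require(doc, "sources")):
        where = f"sources[{i}]"
        sid = str(_require(s, "id", where))
        region = _coords_to_poly(_require(s, "region", where), f"{where}.region")
        events = tuple((float(t), int(c)) for t, c in s.get("schedule", []))
        try:
            schedule = Schedule(events=events)
        except ValueError as exc:
            raise ValueError(f"{where}.schedule: {exc}")
        sources.append(SourceSpec(id=sid, region=region, schedule=schedule))

    targets = []
    for i, t in enumerate(_require(doc, "targets")):
        where = f"targets[{i}]"
        targets.append(
            TargetSpec(id=str(_require(t, "id", where)), region=_coords_to_poly(_require(t, "region", where), f"{where}.region"))
        )

    vp = _require(doc, "velocity_profile")
    try:
        profile = VelocityProfile(
            mean=float(_require(vp, "mean", "velocity_profile")),
            sd=float(_require(vp, "sd", "velocity_profile")),
            lower=float(vp.get("lower", 0.1)),
            upper=float(vp.get("upper", 4.0)),
        )
    except ValueError as exc:
        raise ValueError(f"velocity_profile: {exc}")

    try:
        params = PotentialParams(**{k: float(v) for k, v in doc.get("potential_params", {}).items()})
    except (TypeError, ValueError) as exc:
        raise ValueError(f"potential_params: {exc}")

    matrix = {
        str(sid): {str(tid): float(p) for tid, p in row.items()}
        for sid, row in _require(doc, "source_target_matrix").items()
    }
    try:
        return Scenario(
            extent=tuple(float(c) for c in extent),
            lattice_constant=float(doc.get("lattice_constant", 0.53)),
            obstacles=[_coords_to_poly(c, f"obstacles[{i}]") for i, c in enumerate(doc.get("obstacles", []))],
            sources=sources,
            targets=targets,
            source_target_matrix=matrix,
            velocity_profile=profile,
            potential_params=params,
            duration=float(_require(doc, "duration")),
            time_step=float(doc.get("time_step", 0.1)),
            update_order=str(doc.get("update_order", "oldest_first")),
            recycle={str(k): str(v) for k, v in doc.get("recycle", {}).items()},
        )
    except ValueError as exc:
        raise ValueError(f"scenario config invalid: {exc}")


def load_scenario(path) -> Scenario:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return scenario_from_dict(doc)


def save_scenario(scenario: Scenario, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(scenario_to_dict(scenario), fh, sort_keys=True, default_flow_style=None)


def config_hash(scenario: Scenario) -> str:
    """Short hash of the canonical config text, for reproducibility logs."""
    text = yaml.safe_dump(scenario_to_dict(scenario), sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# trajectory tables
# ---------------------------------------------------------------------------


def write_trajectories(data: TrajectoryDataset, path) -> None:
    data.df.to_csv(path, index=False, float_format="%.6f")


def read_trajectories(path, sampling_interval: float | None = None) -> TrajectoryDataset:
    df = pd.read_csv(path)
    missing = [c for c in ("ped_id", "t", "x", "y") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing} in header")
    for col in ("t", "x", "y"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # header is line 1
            raise ValueError(f"{path}:{line}: malformed value {df[col][bad].iloc[0]!r} in column {col!r}")
        if coerced.isna().any():
            line = int(np.flatnonzero(coerced.isna().to_numpy())[0]) + 2
            raise ValueError(f"{path}:{line}: missing value in column {col!r}")
        df[col] = coerced
    try:
        return TrajectoryDataset(df.reset_index(drop=True), sampling_interval=sampling_interval)
    except ValueError as exc:
        # map the row index in the message to a file line number
        import re

        m = re.search(r"violated at row (\d+)", str(exc))
        if m:
            raise ValueError(f"{path}:{int(m.group(1)) + 2}: {exc}")
        raise


# ---------------------------------------------------------------------------
# synthetic fixtures with known ground truth
# ---------------------------------------------------------------------------


@dataclass
class FixtureSpec:
    """Recipe for a synthetic trajectory dataset with known ground truth.

    ``mode="simulator"`` runs the full engine; ``mode="kinematic"`` moves
    point agents in straight lines at their drawn speeds without exclusion or
    repulsion (obstacle-free geometry assumed) — ideal for estimator unit
    tests because every recovered quantity has an exact known value.
    ``arrival_rates`` (persons/s per source), when given, replace the
    scenario schedules by realized Poisson arrival processes.
    """

    scenario: Scenario
    mode: str = "kinematic"
    arrival_rates: dict[str, float] | None = None
    sample_interval: float = 0.5

    def __post_init__(self) -> None:
        if self.mode not in ("kinematic", "simulator"):
            raise ValueError(f"mode must be kinematic or simulator, got {self.mode!r}")
        if self.sample_interval <= 0:
            raise ValueError(f"sample_interval must be positive, got {self.sample_interval}")


def _uniform_point_in(poly: Polygon, rng: np.random.Generator) -> tuple[float, float]:
    x0, y0, x1, y1 = poly.bounds
    for _ in range(10_000):
        x = x0 + (x1 - x0) * rng.random()
        y = y0 + (y1 - y0) * rng.random()
        if poly.covers(Point(x, y)):
            return x, y
    raise RuntimeError("rejection sampling failed to hit the region polygon")


def _realize_schedules(spec: FixtureSpec, rng: np.random.Generator) -> dict[str, Schedule]:
    out = {}
    for src in spec.scenario.sources:
        if spec.arrival_rates is not None and src.id in spec.arrival_rates:
            rate = spec.arrival_rates[src.id]
            times, t = [], 0.0
            while True:
                t += rng.exponential(1.0 / rate) if rate > 0 else math.inf
                if t >= spec.scenario.duration:
                    break
                times.append(round(t, 3))
            out[src.id] = Schedule(events=tuple((t, 1) for t in times))
        else:
            out[src.id] = src.schedule
    return out


def generate_fixture(spec: FixtureSpec, seed: int) -> tuple[TrajectoryDataset, dict]:
    """Produce a trajectory dataset plus the exact ground truth that made it.

    The ground-truth record holds the per-agent table (id, source, target,
    speed, spawn time), the realized schedules, the velocity profile and the
    source-target matrix used.
    """
    rng = substream(seed, "fixture")
    schedules = _realize_schedules(spec, rng)
    scenario = replace(
        spec.scenario,
        sources=[SourceSpec(s.id, s.region, schedules[s.id]) for s in spec.scenario.sources],
    )

    if spec.mode == "simulator":
        result = run_simulation(scenario, seed)
        truth_agents = result.events[["ped_id", "source", "target", "speed", "spawn_t"]].copy()
        data = result.trajectories
        truth = {
            "agents": truth_agents,
            "schedules": schedules,
            "profile": scenario.velocity_profile,
            "matrix": scenario.source_target_matrix,
            "events": result.events,
        }
        return data, truth

    # kinematic mode
    targets = {t.id: t.region for t in scenario.targets}
    rows_id, rows_t, rows_x, rows_y = [], [], [], []
    agents = []
    next_id = 0
    for src in scenario.sources:
        row = scenario.source_target_matrix[src.id]
        tids = sorted(row)
        probs = np.array([row[k] for k in tids], dtype=float)
        probs /= probs.sum()
        for ev_t, count in schedules[src.id].events:
            for _ in range(count):
                x0, y0 = _uniform_point_in(src.region, rng)
                tid = tids[int(rng.choice(len(tids), p=probs))]
                x1, y1 = _uniform_point_in(targets[tid], rng)
                speed = float(sample_free_flow_speed(scenario.velocity_profile, rng))
                dist = math.hypot(x1 - x0, y1 - y0)
                travel = dist / speed
                ts = np.arange(0.0, travel, spec.sample_interval)
                if len(ts) == 0 or travel - ts[-1] > 1e-9:
                    ts = np.append(ts, travel)
                frac = ts / travel if travel > 0 else np.zeros_like(ts)
                rows_id.extend([next_id] * len(ts))
                rows_t.extend((ev_t + ts).tolist())
                rows_x.extend((x0 + frac * (x1 - x0)).tolist())
                rows_y.extend((y0 + frac * (y1 - y0)).tolist())
                agents.append((next_id, src.id, tid, speed, float(ev_t)))
                next_id += 1
    df = pd.DataFrame({"ped_id": rows_id, "t": rows_t, "x": rows_x, "y": rows_y})
    truth = {
        "agents": pd.DataFrame(agents, columns=["ped_id", "source", "target", "speed", "spawn_t"]),
        "schedules": schedules,
        "profile": scenario.velocity_profile,
        "matrix": scenario.source_target_matrix,
    }
    return TrajectoryDataset(df, sampling_interval=spec.sample_interval), truth
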