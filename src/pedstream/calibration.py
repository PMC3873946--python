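"""Estimation of model inputs from pedestrian trajectory tables.

Everything the simulator needs can be measured: the free-flow velocity
distribution (from trajectory windows with a free path in the direction of
movement, with outlier exclusion and a composite normality check), the
source-target probability matrix and per-source arrival schedules (from
first/last detected positions), the prevailing density-flow relation with a
smooth reference curve, the distribution of distances kept from walls, and —
on top of the reference curve — a derivative-free fit of the repulsion
parameters.  Inputs divide into stationary (topology), quasi-stationary
(velocity profile, density-flow relation, source-target matrix, wall
distances) and dynamic (arrival schedules) classes, which determines how
often each must be re-estimated in a live deployment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from scipy.optimize import minimize
from scipy.spatial import cKDTree
from scipy.stats import norm
from shapely.geometry import Polygon

from pedstream._rng import substream
from pedstream.engine import Scenario, Schedule, VelocityProfile, run_simulation
from pedstream.trajectories import TrajectoryDataset

__all__ = [
    "CalibrationResult",
    "CvmResult",
    "ReferenceCurve",
    "SourceTargetMatrix",
    "TrajectoryDataset",
    "VelocityProfile",
    "WallDistanceResult",
    "calibrate_potentials",
    "cvm_normality_test",
    "estimate_schedule",
    "estimate_source_target_matrix",
    "extract_free_flow_samples",
    "filter_outliers",
    "fit_velocity_profile",
    "measure_density_flow",
    "measure_wall_distances",
    "smooth_reference_curve",
]


def _as_regions(regions) -> dict[str, Polygon]:
    if isinstance(regions, Mapping):
        items = regions.items()
    else:
        items = regions
    out = {}
    for rid, poly in items:
        out[str(rid)] = poly if isinstance(poly, Polygon) else Polygon(poly)
    return out


# ---------------------------------------------------------------------------
# free-flow velocity distribution
# ---------------------------------------------------------------------------


def extract_free_flow_samples(
    data: TrajectoryDataset,
    free_radius: float = 2.0,
    window: float = 2.0,
) -> np.ndarray:
    """One free-flow speed sample per pedestrian that ever walks freely.

    For every pedestrian and every sliding window of length ``window`` the
    displacement/elapsed-time speed is computed.  A window qualifies as
    free-flow iff, at the window midpoint, no other pedestrian is inside the
    forward half-plane (relative to the direction of motion) within
    ``free_radius`` meters.  A pedestrian's sample is the median of its
    qualifying window speeds; pedestrians with no qualifying window (or no
    measurable direction of motion) contribute nothing.
    """
    if len(data) == 0:
        raise ValueError("empty trajectory dataset")
    by_ped = data.by_pedestrian()

    # Snapshot cache: positions of everyone at window-midpoint times, binned
    # to a fixed resolution so nearby midpoints share one KD-tree.
    bin_w = data.sampling_interval or 0.5
    cache: dict[int, tuple[list, np.ndarray, cKDTree | None]] = {}

    def snapshot(tm: float):
        key = int(round(tm / bin_w))
        if key not in cache:
            ids, pos = data.positions_at(key * bin_w)
            tree = cKDTree(pos) if len(pos) else None
            cache[key] = (ids, pos, tree)
        return cache[key]

    samples = []
    for pid, (tt, xx, yy) in by_ped.items():
        if len(tt) < 2:
            continue
        speeds = []
        for j in range(len(tt)):
            t0 = tt[j]
            t1 = t0 + window
            if t1 > tt[-1] + 1e-9:
                break
            x0, y0 = np.interp(t0, tt, xx), np.interp(t0, tt, yy)
            x1, y1 = np.interp(t1, tt, xx), np.interp(t1, tt, yy)
            disp = math.hypot(x1 - x0, y1 - y0)
            if disp < 1e-9:
                continue  # no direction of motion
            direction = np.array([(x1 - x0) / disp, (y1 - y0) / disp])
            tm = 0.5 * (t0 + t1)
            ids, pos, tree = snapshot(tm)
            pm = np.array([np.interp(tm, tt, xx), np.interp(tm, tt, yy)])
            free = True
            if tree is not None:
                for k in tree.query_ball_point(pm, r=free_radius):
                    if ids[k] == pid:
                        continue
                    # closed half-plane: walking exactly abreast still blocks
                    if float((pos[k] - pm) @ direction) >= -1e-9:
                        free = False
                        break
            if free:
                speeds.append(disp / window)
        if speeds:
            samples.append(float(np.median(speeds)))
    return np.asarray(samples)


def filter_outliers(
    samples,
    lower: float = 0.1,
    upper: float = 4.0,
) -> tuple[np.ndarray, int]:
    """Drop dawdlers below ``lower`` and runners above ``upper`` m/s."""
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValueError("no speed samples to filter")
    keep = (samples >= lower) & (samples <= upper)
    kept = samples[keep]
    if kept.size == 0:
        raise ValueError(f"all {samples.size} samples fall outside [{lower}, {upper}] m/s")
    return kept, int(samples.size - kept.size)


def fit_velocity_profile(
    samples,
    lower: float = 0.1,
    upper: float = 4.0,
    outliers_removed: int = 0,
) -> VelocityProfile:
    """Normal fit (sample mean, n-1 standard deviation) of speed samples."""
    samples = np.asarray(samples, dtype=float)
    if samples.size < 2:
        raise ValueError(f"need at least 2 samples to fit a profile, got {samples.size}")
    return VelocityProfile(
        mean=float(np.mean(samples)),
        sd=float(np.std(samples, ddof=1)),
        lower=lower,
        upper=upper,
        n_samples=int(samples.size),
        outliers_removed=outliers_removed,
    )


@dataclass(frozen=True)
class CvmResult:
    statistic: float
    pvalue: float
    reject: bool


def cvm_statistic(samples: np.ndarray, mean: float, sd: float) -> float:
    """Cramer-von Mises W^2 against a given normal distribution."""
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    f = norm.cdf(x, mean, sd)
    i = np.arange(1, n + 1)
    return float(1.0 / (12 * n) + np.sum((f - (2 * i - 1) / (2 * n)) ** 2))


def cvm_normality_test(
    samples,
    alpha: float = 0.005,
    n_boot: int = 999,
    random_state: int = 0,
) -> CvmResult:
    """Composite normality test (mean and sd estimated) via Cramer-von Mises.

    The null distribution of W^2 with estimated parameters is obtained by a
    parametric bootstrap: ``n_boot`` standard-normal samples of the same size
    are drawn, each standardized by its own estimates, and the p-value is the
    add-one bootstrap fraction of replicate statistics at least as large as
    the observed one.  (W^2 is location/scale invariant under re-estimation,
    so standard normal replicates suffice.)
    """
    samples = np.asarray(samples, dtype=float)
    n = samples.size
    if n < 8:
        raise ValueError(f"need at least 8 samples, got {n}")
    mean = float(np.mean(samples))
    sd = float(np.std(samples, ddof=1))
    if sd == 0.0:
        raise ValueError("constant samples: normal CDF fit is undefined")
    w2 = cvm_statistic(samples, mean, sd)

    rng = np.random.default_rng(random_state)
    reps = rng.standard_normal((n_boot, n))
    mu = reps.mean(axis=1, keepdims=True)
    s = reps.std(axis=1, ddof=1, keepdims=True)
    z = np.sort((reps - mu) / s, axis=1)
    f = norm.cdf(z)
    i = np.arange(1, n + 1)
    w2_boot = 1.0 / (12 * n) + np.sum((f - (2 * i - 1) / (2 * n)) ** 2, axis=1)
    pvalue = float((1 + np.sum(w2_boot >= w2)) / (n_boot + 1))
    return CvmResult(statistic=w2, pvalue=pvalue, reject=bool(pvalue < alpha))


# ---------------------------------------------------------------------------
# source-target matrix and schedules
# ---------------------------------------------------------------------------


@dataclass
class SourceTargetMatrix:
    """Row-stochastic source-to-target choice probabilities with raw counts.

    ``probs`` holds only rows for sources with at least one assigned
    pedestrian (each row sums to 1 exactly); ``counts`` covers all sources.
    """

    probs: pd.DataFrame
    counts: pd.DataFrame
    n_unassigned: int

    def row(self, source_id: str) -> dict[str, float]:
        return self.probs.loc[source_id].to_dict()


def _check_disjoint(regions: dict[str, Polygon], kind: str) -> None:
    items = list(regions.items())
    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            if items[i][1].intersection(items[j][1]).area > 1e-12:
                raise ValueError(f"{kind} regions {items[i][0]!r} and {items[j][0]!r} overlap")


def estimate_source_target_matrix(
    data: TrajectoryDataset,
    sources,
    targets,
) -> SourceTargetMatrix:
    """Count first-seen-in-source / last-seen-in-target pairs and normalize.

    A pedestrian's source is the region containing its first record, its
    target the region containing its last; pedestrians whose endpoints fall
    in no region are excluded from the probabilities and counted as
    unassigned.
    """
    sources = _as_regions(sources)
    targets = _as_regions(targets)
    _check_disjoint(sources, "source")
    _check_disjoint(targets, "target")

    counts = pd.DataFrame(0, index=sorted(sources), columns=sorted(targets), dtype=int)
    n_unassigned = 0
    for pid, (tt, xx, yy) in data.by_pedestrian().items():
        first = shapely.Point(xx[0], yy[0])
        last = shapely.Point(xx[-1], yy[-1])
        src = next((sid for sid, poly in sources.items() if poly.covers(first)), None)
        tgt = next((tid for tid, poly in targets.items() if poly.covers(last)), None)
        if src is None or tgt is None:
            n_unassigned += 1
            continue
        counts.loc[src, tgt] += 1
    row_sums = counts.sum(axis=1)
    if int(row_sums.sum()) == 0:
        raise ValueError("no pedestrian could be assigned to a (source, target) pair")
    assigned = counts.loc[row_sums > 0]
    probs = assigned.div(assigned.sum(axis=1), axis=0)
    return SourceTargetMatrix(probs=probs, counts=counts, n_unassigned=n_unassigned)


def estimate_schedule(
    data: TrajectoryDataset,
    sources,
    bin: float = 2.0,
) -> dict[str, Schedule]:
    """Arrival events per source: first-record times binned to ``bin`` seconds."""
    if bin <= 0:
        raise ValueError(f"bin must be positive, got {bin}")
    sources = _as_regions(sources)
    arrivals: dict[str, list[float]] = {sid: [] for sid in sources}
    for pid, (tt, xx, yy) in data.by_pedestrian().items():
        first = shapely.Point(xx[0], yy[0])
        for sid, poly in sources.items():
            if poly.covers(first):
                arrivals[sid].append(float(tt[0]))
                break
    schedules = {}
    for sid, times in arrivals.items():
        events: list[tuple[float, int]] = []
        if times:
            bins = np.floor(np.asarray(times) / bin).astype(int)
            for b in sorted(set(bins)):
                events.append((float(b * bin), int(np.sum(bins == b))))
        schedules[sid] = Schedule(events=tuple(events))
    return schedules


# ---------------------------------------------------------------------------
# density-flow relation
# ---------------------------------------------------------------------------


def measure_density_flow(
    data: TrajectoryDataset,
    area,
    sample_interval: float = 2.0,
    speed_half_window: float = 0.5,
) -> pd.DataFrame:
    """Sample (density, specific flow) pairs inside ``area``.

    At each sample time, density is the number of pedestrians inside the
    polygon divided by its area (persons/m^2) and flow is density times the
    mean instantaneous speed of those pedestrians (persons/(m s), i.e.
    specific flow).  Only instants with at least one pedestrian inside yield
    a sample.
    """
    area = area if isinstance(area, Polygon) else Polygon(area)
    if area.area <= 0:
        raise ValueError("measurement polygon has zero area")
    t0, t1 = data.time_range
    rows = []
    t = math.ceil(t0 / sample_interval) * sample_interval
    while t <= t1 + 1e-9:
        ids, pos = data.positions_at(t)
        if len(ids):
            inside = shapely.intersects_xy(area, pos[:, 0], pos[:, 1])
            n_in = int(inside.sum())
            if n_in > 0:
                sid, speeds = data.speeds_at(t, speed_half_window)
                speed_of = dict(zip(sid, speeds))
                v = [speed_of[i] for f, i in zip(inside, ids) if f and i in speed_of]
                if v:
                    rho = n_in / area.area
                    rows.append((t, rho, rho * float(np.mean(v))))
        t += sample_interval
    return pd.DataFrame(rows, columns=["t", "density", "flow"])


@dataclass
class ReferenceCurve:
    """Measured (density, flow) scatter with a smooth approximation.

    ``band`` is the 90th percentile of absolute residuals around the smooth
    curve — the half-width within which 90% of the measured points lie.
    """

    density: np.ndarray
    flow: np.ndarray
    grid_density: np.ndarray
    grid_flow: np.ndarray
    band: float

    def smooth(self, rho) -> np.ndarray:
        return np.interp(rho, self.grid_density, self.grid_flow)

    __call__ = smooth


def smooth_reference_curve(
    samples: pd.DataFrame,
    bandwidth_frac: float = 0.3,
    grid_points: int = 50,
) -> ReferenceCurve:
    """Locally weighted (local-linear) smoothing of the density-flow scatter.

    The kernel bandwidth is ``bandwidth_frac`` of the sampled density range.
    """
    rho = np.asarray(samples["density"], dtype=float)
    flow = np.asarray(samples["flow"], dtype=float)
    if rho.size < 5:
        raise ValueError(f"need at least 5 (density, flow) samples, got {rho.size}")
    span = float(rho.max() - rho.min())
    if span <= 0:
        raise ValueError("all samples share one density; the curve is undefined")
    from statsmodels.nonparametric.kernel_regression import KernelReg

    h = bandwidth_frac * span
    reg = KernelReg(endog=flow, exog=rho, var_type="c", reg_type="ll", bw=[h])
    grid = np.linspace(rho.min(), rho.max(), grid_points)
    grid_flow, _ = reg.fit(grid)
    fitted, _ = reg.fit(rho)
    band = float(np.percentile(np.abs(flow - fitted), 90))
    return ReferenceCurve(density=rho, flow=flow, grid_density=grid, grid_flow=np.asarray(grid_flow), band=band)


# ---------------------------------------------------------------------------
# wall distances
# ---------------------------------------------------------------------------


@dataclass
class WallDistanceResult:
    samples: np.ndarray
    quantiles: dict[float, float]


def measure_wall_distances(data: TrajectoryDataset, obstacles: Sequence) -> WallDistanceResult:
    """Distance from every trajectory record to the nearest obstacle boundary."""
    obstacles = [p if isinstance(p, Polygon) else Polygon(p) for p in obstacles]
    if not obstacles:
        raise ValueError("obstacles must be nonempty")
    boundary = shapely.unary_union([p.boundary for p in obstacles])
    pts = shapely.points(data.df[["x", "y"]].to_numpy(dtype=float))
    d = shapely.distance(boundary, pts)
    qs = (0.05, 0.25, 0.5, 0.75, 0.95)
    return WallDistanceResult(
        samples=np.asarray(d, dtype=float),
        quantiles={q: float(np.quantile(d, q)) for q in qs},
    )


# ---------------------------------------------------------------------------
# potential-parameter calibration against the reference curve
# ---------------------------------------------------------------------------


@dataclass
class CalibrationResult:
    params: object  # PotentialParams
    objective: float
    n_evaluations: int


def calibrate_potentials(
    scenario: Scenario,
    reference: ReferenceCurve,
    seeds: Sequence[int],
    budget: int = 40,
    measure_area: Polygon | None = None,
    sample_interval: float = 2.0,
    x0: tuple[float, float] | None = None,
) -> CalibrationResult:
    """Fit (agent_amplitude, agent_range) so the simulated density-flow curve
    matches the reference.

    A derivative-free simplex search minimizes the mean squared deviation
    between the smooth reference and the (density, flow) samples measured on
    simulator output, pooled over ``seeds``.  ``budget`` caps objective
    evaluations; a previous result's parameters make a good warm start
    because the relation is quasi-stationary.
    """
    if measure_area is None:
        x_min, y_min, x_max, y_max = scenario.extent
        measure_area = shapely.box(x_min, y_min, x_max, y_max)
    base = scenario.potential_params
    if x0 is None:
        x0 = (base.agent_amplitude, base.agent_range)

    evaluations = {"n": 0, "feasible": 0}

    def objective(x) -> float:
        amplitude, decay = float(x[0]), float(x[1])
        if amplitude <= 0 or decay <= 0 or decay > base.agent_cutoff:
            return math.inf
        evaluations["n"] += 1
        params = replace(base, agent_amplitude=amplitude, agent_range=decay)
        sq = []
        for seed in seeds:
            sim = run_simulation(replace_params(scenario, params), int(seed))
            df = measure_density_flow(sim.trajectories, measure_area, sample_interval)
            if len(df):
                resid = df["flow"].to_numpy() - reference.smooth(df["density"].to_numpy())
                sq.extend(resid**2)
        if not sq:
            return math.inf
        evaluations["feasible"] += 1
        return float(np.mean(sq))

    f0 = objective(np.asarray(x0, dtype=float))
    if budget <= 1:
        if not math.isfinite(f0):
            raise RuntimeError("calibration budget exhausted without a feasible evaluation")
        return CalibrationResult(
            params=replace(base, agent_amplitude=x0[0], agent_range=x0[1]),
            objective=f0,
            n_evaluations=evaluations["n"],
        )

    res = minimize(
        objective,
        np.asarray(x0, dtype=float),
        method="Nelder-Mead",
        options={"maxfev": budget - 1, "xatol": 1e-3, "fatol": 1e-6},
    )
    if evaluations["feasible"] == 0:
        raise RuntimeError("calibration budget exhausted without a feasible evaluation")
    best_x, best_f = (res.x, float(res.fun)) if float(res.fun) <= f0 else (np.asarray(x0), f0)
    return CalibrationResult(
        params=replace(base, agent_amplitude=float(best_x[0]), agent_range=float(best_x[1])),
        objective=best_f,
        n_evaluations=evaluations["n"],
    )


def replace_params(scenario: Scenario, params) -> Scenario:
    """Copy of a scenario with different potential parameters."""
    return replace(scenario, potential_params=params)
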