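"""Estimators: free-flow speeds, outliers, normality, matrices, schedules,
density-flow curves, wall distances and potential calibration."""

import math

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from conftest import corridor_scenario
from pedstream.calibration import (
    TrajectoryDataset,
    calibrate_potentials,
    cvm_normality_test,
    cvm_statistic,
    estimate_schedule,
    estimate_source_target_matrix,
    extract_free_flow_samples,
    filter_outliers,
    fit_velocity_profile,
    measure_density_flow,
    measure_wall_distances,
    smooth_reference_curve,
)
from pedstream.engine import Scenario, Schedule, SourceSpec, TargetSpec, VelocityProfile
from pedstream.scenario_io import FixtureSpec, generate_fixture


def walk(pid, t0, x0, y0, vx, vy, n, dt=0.5):
    """Rows for one pedestrian moving at constant velocity."""
    return [
        {"ped_id": pid, "t": t0 + k * dt, "x": x0 + vx * k * dt, "y": y0 + vy * k * dt}
        for k in range(n)
    ]


def dataset(rows, interval=0.5):
    return TrajectoryDataset(pd.DataFrame(rows), sampling_interval=interval)


# ---------------------------------------------------------------------------
# free-flow extraction
# ---------------------------------------------------------------------------


def test_single_walker_yields_their_speed():
    data = dataset(walk("p1", 0.0, 0.0, 0.0, 1.0, 0.0, 9))
    samples = extract_free_flow_samples(data, window=2.0)
    assert len(samples) == 1
    assert math.isclose(samples[0], 1.0, rel_tol=1e-9)


def test_walking_abreast_is_never_free():
    rows = walk("a", 0.0, 0.0, 0.0, 1.0, 0.0, 9) + walk("b", 0.0, 0.0, 0.5, 1.0, 0.0, 9)
    samples = extract_free_flow_samples(dataset(rows), free_radius=2.0, window=2.0)
    assert len(samples) == 0


def test_pedestrian_behind_does_not_block():
    # follower 1.5 m behind the leader: the leader's forward half-plane is
    # clear (one sample), while the follower sees the leader ahead (blocked)
    rows = walk("lead", 0.0, 1.5, 0.0, 1.0, 0.0, 9) + walk("tail", 0.0, 0.0, 0.0, 1.0, 0.0, 9)
    samples = extract_free_flow_samples(dataset(rows), free_radius=2.0, window=2.0)
    assert len(samples) == 1  # only the leader is free


def test_sparse_crowd_speeds_recovered_within_one_percent():
    rng = np.random.default_rng(0)
    rows = []
    true_speeds = {}
    for i in range(25):
        v = rng.uniform(0.8, 1.6)
        y = 3.0 * i  # well separated lanes
        rows += walk(f"p{i}", 0.0, 0.0, y, v, 0.0, 12)
        true_speeds[f"p{i}"] = v
    samples = extract_free_flow_samples(dataset(rows))
    assert len(samples) == 25
    assert np.allclose(np.sort(samples), np.sort(list(true_speeds.values())), rtol=0.01)


def test_empty_dataset_rejected():
    with pytest.raises(ValueError, match="empty"):
        extract_free_flow_samples(TrajectoryDataset(pd.DataFrame(columns=["ped_id", "t", "x", "y"])))


# ---------------------------------------------------------------------------
# outlier filtering and profile fitting
# ---------------------------------------------------------------------------


def test_outlier_bounds_drop_dawdlers_and_runners():
    kept, removed = filter_outliers([0.05, 1.0, 5.0])
    assert list(kept) == [1.0]
    assert removed == 2


def test_filter_is_identity_inside_bounds_and_idempotent():
    samples = np.array([0.5, 1.0, 2.0, 3.9])
    kept, removed = filter_outliers(samples)
    assert removed == 0 and np.array_equal(kept, samples)
    kept2, removed2 = filter_outliers(kept)
    assert removed2 == 0 and np.array_equal(kept2, kept)


def test_fig5_structured_fixture_214_to_202():
    """214 speed samples with 12 planted outliers leave 202 after filtering."""
    rng = np.random.default_rng(1)
    good = np.clip(rng.normal(1.04, 0.45, size=202), 0.12, 3.9)
    outliers = np.concatenate([np.full(11, 0.05), [4.5]])
    samples = rng.permutation(np.concatenate([good, outliers]))
    assert len(samples) == 214
    kept, removed = filter_outliers(samples)
    assert len(kept) == 202 and removed == 12


def test_all_samples_outside_bounds_rejected():
    with pytest.raises(ValueError, match="outside"):
        filter_outliers([0.01, 0.02])


def test_profile_fit_constant_and_morning_recovery():
    p = fit_velocity_profile([1.0, 1.0])
    assert p.mean == 1.0 and p.sd == 0.0
    rng = np.random.default_rng(2)
    draws = rng.normal(0.97, 0.29, size=10_000)
    p = fit_velocity_profile(draws)
    assert abs(p.mean - 0.97) < 0.01
    assert abs(p.sd - 0.29) < 0.01


def test_profile_fit_is_affine_equivariant():
    rng = np.random.default_rng(3)
    s = rng.uniform(0.5, 2.0, size=50)
    p = fit_velocity_profile(s)
    q = fit_velocity_profile(0.5 * s + 0.2)
    assert math.isclose(q.mean, 0.5 * p.mean + 0.2, rel_tol=1e-12)
    assert math.isclose(q.sd, 0.5 * p.sd, rel_tol=1e-12)


# ---------------------------------------------------------------------------
# Cramer-von Mises normality
# ---------------------------------------------------------------------------


def test_cvm_statistic_matches_manual_formula_evaluation():
    samples = [0.62, 0.81, 0.93, 1.02, 1.05, 1.12, 1.19, 1.28, 1.44, 1.61]
    mean = sum(samples) / 10
    sd = math.sqrt(sum((s - mean) ** 2 for s in samples) / 9)
    from scipy.stats import norm

    manual = 1.0 / 120.0
    for i, s in enumerate(sorted(samples), start=1):
        manual += (norm.cdf(s, mean, sd) - (2 * i - 1) / 20.0) ** 2
    assert abs(cvm_statistic(np.array(samples), mean, sd) - manual) < 1e-10


def test_cvm_holds_its_level_on_normal_data():
    rejections = 0
    for seed in range(50):
        x = np.random.default_rng(seed).normal(1.0, 0.3, size=500)
        res = cvm_normality_test(x, alpha=0.005, random_state=seed)
        rejections += res.reject
    assert rejections <= 2  # ~0.5% level


def test_cvm_rejects_uniform_with_high_power():
    rejections = 0
    for seed in range(20):
        x = np.random.default_rng(seed).uniform(0, 2, size=500)
        res = cvm_normality_test(x, alpha=0.005, random_state=seed)
        rejections += res.reject
    assert rejections >= 18  # power > 0.9


def test_cvm_rejects_degenerate_inputs():
    with pytest.raises(ValueError, match="at least 8"):
        cvm_normality_test([1.0] * 5)
    with pytest.raises(ValueError, match="constant"):
        cvm_normality_test([1.0] * 10)


# ---------------------------------------------------------------------------
# source-target matrix and schedules
# ---------------------------------------------------------------------------

REGIONS_A = {"A": box(0, 0, 1, 5)}
REGIONS_AB = {"A": box(0, 0, 1, 5), "B": box(0, 6, 1, 11)}
TARGETS_12 = {"T1": box(9, 0, 10, 5), "T2": box(9, 6, 10, 11)}


def crossing(pid, y0, y1, t0=0.0):
    n = 10
    return [
        {"ped_id": pid, "t": t0 + k, "x": 0.5 + k, "y": y0 + (y1 - y0) * k / (n - 1)}
        for k in range(n)
    ]


def test_single_route_gives_degenerate_row():
    rows = [r for i in range(5) for r in crossing(f"p{i}", 2.0, 2.0)]
    m = estimate_source_target_matrix(dataset(rows), REGIONS_A, TARGETS_12)
    assert m.probs.loc["A", "T1"] == 1.0
    assert m.probs.loc["A", "T2"] == 0.0


def test_seventy_thirty_split_counted_exactly():
    rows = []
    for i in range(10):
        rows += crossing(f"p{i}", 2.0, 2.0 if i < 7 else 8.0)
    m = estimate_source_target_matrix(dataset(rows), REGIONS_A, TARGETS_12)
    assert m.probs.loc["A", "T1"] == 0.7
    assert m.probs.loc["A", "T2"] == 0.3
    assert m.counts.loc["A"].sum() == 10
    assert abs(m.probs.loc["A"].sum() - 1.0) < 1e-12


def test_pedestrian_outside_all_regions_is_excluded_and_counted():
    rows = crossing("in", 2.0, 2.0) + crossing("out", 2.0, 2.0, t0=100.0)
    for r in rows:
        if r["ped_id"] == "out":
            r["y"] += 20.0  # starts and ends outside every region
    m = estimate_source_target_matrix(dataset(rows), REGIONS_A, TARGETS_12)
    assert m.n_unassigned == 1
    assert m.counts.to_numpy().sum() == 1


def test_overlapping_regions_rejected():
    with pytest.raises(ValueError, match="overlap"):
        estimate_source_target_matrix(
            dataset(crossing("p", 2.0, 2.0)),
            {"A": box(0, 0, 1, 5), "A2": box(0, 4, 1, 9)},
            TARGETS_12,
        )


def test_schedule_bins_first_detection_times():
    rows = []
    for i, t0 in enumerate([0.0, 0.4, 0.9, 1.3, 1.9]):
        rows += crossing(f"p{i}", 2.0, 2.0, t0=t0)
    sched = estimate_schedule(dataset(rows), REGIONS_AB, bin=2.0)
    assert sched["A"].events == ((0.0, 5),)
    assert sched["B"].events == ()


def test_poisson_arrival_totals_recovered():
    scn = Scenario(
        extent=(0, 0, 30, 10),
        sources=[SourceSpec("A", box(0.3, 0.5, 2.0, 9.5), Schedule(events=()))],
        targets=[TargetSpec("T", box(28.0, 0.5, 29.7, 9.5))],
        source_target_matrix={"A": {"T": 1.0}},
        velocity_profile=VelocityProfile(mean=1.3, sd=0.2),
        duration=300.0,
    )
    data, truth = generate_fixture(
        FixtureSpec(scenario=scn, mode="kinematic", arrival_rates={"A": 0.5}), seed=8
    )
    total_truth = truth["schedules"]["A"].total
    assert abs(total_truth - 150) <= 3 * math.sqrt(150)
    sched = estimate_schedule(data, {"A": box(0.3, 0.5, 2.0, 9.5)}, bin=2.0)
    assert sched["A"].total == total_truth


# ---------------------------------------------------------------------------
# density-flow measurement and smoothing
# ---------------------------------------------------------------------------


def test_single_pedestrian_unit_area_gives_unit_density_and_flow():
    area = box(3.5, -0.5, 4.5, 0.5)  # 1 m^2 straddling the walker's path
    rows = walk("p", 0.0, 0.0, 0.0, 1.0, 0.0, 21)
    df = measure_density_flow(dataset(rows), area, sample_interval=2.0)
    hit = df[np.isclose(df["t"], 4.0)]
    assert len(hit) == 1
    assert math.isclose(hit["density"].iloc[0], 1.0, rel_tol=1e-9)
    assert math.isclose(hit["flow"].iloc[0], 1.0, rel_tol=1e-6)


def test_empty_area_yields_no_samples():
    area = box(50, 50, 51, 51)
    rows = walk("p", 0.0, 0.0, 0.0, 1.0, 0.0, 9)
    df = measure_density_flow(dataset(rows), area)
    assert len(df) == 0


def test_zero_area_polygon_rejected():
    rows = walk("p", 0.0, 0.0, 0.0, 1.0, 0.0, 9)
    with pytest.raises(ValueError, match="zero area"):
        measure_density_flow(dataset(rows), [(0, 0), (1, 0), (2, 0)])


def test_prescribed_speed_density_law_recovered():
    """Columns of walkers at speed v(rho) recover J = rho * v(rho) within 5%."""
    area = box(0, 0, 4, 4)

    def v_of_rho(rho):
        return 1.4 * (1 - rho / 5.0)

    rows = []
    pid = 0
    for block, n in enumerate((4, 8, 16, 24)):  # rho = n/16
        rho = n / 16.0
        v = v_of_rho(rho)
        t0 = block * 100.0
        for k in range(n):
            x0, y0 = 0.2 + (k % 4) * 1.0, 0.2 + (k // 4) * 0.6
            rows += walk(pid, t0, x0, y0, 0.0, v, 6)
            pid += 1
    df = measure_density_flow(dataset(rows), area, sample_interval=2.0)
    for block, n in enumerate((4, 8, 16, 24)):
        rho = n / 16.0
        # first sample instant only: everyone is still inside the area there
        got = df[np.isclose(df["t"], block * 100.0)]
        assert len(got) >= 1
        assert np.allclose(got["flow"], rho * v_of_rho(rho), rtol=0.05)


def test_smooth_curve_reproduces_exact_line():
    rho = np.linspace(0.1, 2.0, 20)
    samples = pd.DataFrame({"density": rho, "flow": 0.5 + 0.8 * rho})
    curve = smooth_reference_curve(samples)
    assert np.allclose(curve.smooth(rho), 0.5 + 0.8 * rho, atol=1e-6)
    assert curve.band < 1e-6


def test_smooth_curve_band_matches_noise_quantile():
    rng = np.random.default_rng(4)
    rho = np.linspace(0.1, 2.0, 400)
    noise = rng.uniform(-0.15, 0.15, size=rho.size)
    samples = pd.DataFrame({"density": rho, "flow": 1.0 + 0.5 * rho + noise})
    curve = smooth_reference_curve(samples)
    expected_band = np.percentile(np.abs(noise), 90)
    assert abs(curve.band - expected_band) < 0.03


def test_smooth_curve_total_on_nonmonotone_scatter():
    rng = np.random.default_rng(5)
    rho = rng.uniform(0.1, 2.0, size=60)
    flow = rng.uniform(0.0, 1.5, size=60)
    curve = smooth_reference_curve(pd.DataFrame({"density": rho, "flow": flow}))
    grid = np.linspace(rho.min(), rho.max(), 200)
    assert np.all(np.isfinite(curve.smooth(grid)))


def test_degenerate_density_scatter_rejected():
    samples = pd.DataFrame({"density": [1.0] * 6, "flow": np.arange(6.0)})
    with pytest.raises(ValueError, match="one density"):
        smooth_reference_curve(samples)


# ---------------------------------------------------------------------------
# wall distances
# ---------------------------------------------------------------------------


def test_walking_parallel_to_wall_at_one_meter():
    wall = box(0, 2, 10, 3)
    rows = walk("p", 0.0, 0.0, 1.0, 1.0, 0.0, 9)
    res = measure_wall_distances(dataset(rows), [wall])
    assert np.allclose(res.samples, 1.0)
    assert res.quantiles[0.5] == 1.0


def test_no_obstacles_rejected():
    rows = walk("p", 0.0, 0.0, 1.0, 1.0, 0.0, 9)
    with pytest.raises(ValueError, match="nonempty"):
        measure_wall_distances(dataset(rows), [])


def test_mixed_clearances_quantiles_match_construction():
    wall = box(0, -1, 100, 0)
    rows = []
    for i, clearance in enumerate([0.5, 1.0, 1.5, 2.0]):
        rows += walk(f"p{i}", 0.0, i * 20.0, clearance, 1.0, 0.0, 5)
    res = measure_wall_distances(dataset(rows), [wall])
    assert res.quantiles[0.5] == np.quantile([0.5] * 5 + [1.0] * 5 + [1.5] * 5 + [2.0] * 5, 0.5)


# ---------------------------------------------------------------------------
# potential calibration against a reference curve
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def corridor_reference():
    from pedstream.engine import run_simulation

    scn = corridor_scenario(
        length=14.0,
        width=2.5,
        speed_mean=1.3,
        speed_sd=0.2,
        schedule=tuple((float(t), 2) for t in range(0, 30, 2)),
        duration=40.0,
    )
    area = box(4.0, 0.0, 10.0, 2.5)
    sim = run_simulation(scn, 123)
    samples = measure_density_flow(sim.trajectories, area)
    return scn, area, smooth_reference_curve(samples, bandwidth_frac=0.5)


def test_budget_one_returns_starting_point(corridor_reference):
    scn, area, curve = corridor_reference
    res = calibrate_potentials(scn, curve, seeds=[7], budget=1, measure_area=area)
    assert res.params.agent_amplitude == scn.potential_params.agent_amplitude
    assert res.params.agent_range == scn.potential_params.agent_range
    assert res.objective >= 0.0 and math.isfinite(res.objective)


def test_simplex_search_does_not_worsen_the_start(corridor_reference):
    scn, area, curve = corridor_reference
    start = calibrate_potentials(scn, curve, seeds=[7], budget=1, measure_area=area)
    fitted = calibrate_potentials(scn, curve, seeds=[7], budget=8, measure_area=area)
    assert fitted.objective <= start.objective + 1e-12
    assert fitted.objective >= 0.0
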