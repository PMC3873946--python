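# pedstream

Pedestrian stream simulation with a calibration-and-validation toolchain,
for crowd-safety engineers and researchers who need simulations that can be
tied to measurements rather than to literature defaults.

Crowd accidents happen at density hot spots, and a simulation is only useful
for planning or short-term warning if it reproduces where and when those hot
spots occur. `pedstream` implements a benchmark cellular automaton on a
hexagonal lattice (cell spacing 0.53 m, one body diameter): virtual
pedestrians are attracted to their targets by a *floor field* — the arrival
time of a wave front expanding from the target through obstacle-free space,
so each agent follows a shortest obstacle-free path — and repelled by other
pedestrians and obstacles through radially symmetric potentials
`A e^{-r/λ}` with hard cutoffs. A sequential update scheme selects each
agent with frequency proportional to its personal free-flow speed `v ~
N(μ, σ²)` truncated to `[0.1, 4.0]` m/s, so on average everyone walks at
their preferred speed while the path is free, and collisions are impossible
by construction.

Around the simulator sits the methodology that makes it predictive:

- **Calibration** (`pedstream.calibration`): estimate every model input from
  trajectory tables `(ped_id, t, x, y)` — the free-flow velocity
  distribution (free-path windows, 0.1/4.0 m/s outlier rules, Cramér–von
  Mises normality check at the 0.5% level), the source–target probability
  matrix, per-source arrival schedules, the density–flow relation
  (fundamental diagram) with a smooth reference curve, wall-distance
  distributions, and a simplex fit of the repulsion parameters against the
  reference curve.
- **Validation** (`pedstream.validation`): cover the scene with 1 m × 1 m
  tiles sampled every 2 s and score observed vs. simulated densities with
  the fitness `F(t) = 1 / (ε + Σ_k |ρ_obs(k,t) − ρ_sim(k,t)|)`, summed over
  time; plus a ±10% parameter sensitivity analysis.
- **Synthetic fixtures** (`pedstream.scenario_io`): trajectory datasets with
  exact known ground truth, standing in for video-tracking data.

## Worked example

A 20 m × 12 m station hall: a train arrival feeds five pulses of 12
passengers onto the platform edge, 70% head to the east exit and 30% to the
south exit, skirting two food stalls; a trickle of background pedestrians
crosses the hall. Simulate it, then run the calibration estimators on the
simulator's own output:

```python
from shapely.geometry import box
from pedstream.scenario_io import load_scenario
from pedstream.engine import run_simulation
from pedstream.calibration import (extract_free_flow_samples, filter_outliers,
                                   fit_velocity_profile, estimate_source_target_matrix)
from pedstream.validation import tile_densities, fitness

scenario = load_scenario("examples/station_hall.yaml")
result = run_simulation(scenario, seed=1)
print(f"simulated {len(result.events)} pedestrians over {scenario.duration:.0f} s")

samples = extract_free_flow_samples(result.trajectories, free_radius=2.0)
kept, removed = filter_outliers(samples)            # 0.1 / 4.0 m/s bounds
profile = fit_velocity_profile(kept, outliers_removed=removed)
print(f"free-flow speed: mean {profile.mean:.2f} m/s, sd {profile.sd:.2f} m/s "
      f"({profile.n_samples} samples, {removed} outliers removed)")

sources = {"platform": box(0.3, 1.0, 1.6, 11.0)}
targets = {"exit_east": box(19.2, 4.0, 19.8, 8.0), "exit_south": box(6.0, 0.2, 9.0, 0.8)}
matrix = estimate_source_target_matrix(result.trajectories, sources, targets)
print("platform row:", {k: round(v, 2) for k, v in matrix.row("platform").items()})

observed = tile_densities(result.trajectories, scenario.extent, tile=1.0, interval=2.0)
replica = run_simulation(scenario, seed=2)
simulated = tile_densities(replica.trajectories, scenario.extent, times=observed.times)
print(f"fitness vs an independent seed: {fitness(observed, simulated).overall:.2f}")
```

prints

```
simulated 69 pedestrians over 180 s
free-flow speed: mean 0.94 m/s, sd 0.45 m/s (52 samples, 0 outliers removed)
platform row: {'exit_east': 0.68, 'exit_south': 0.32}
fitness vs an independent seed: 15000017.72
```

Reading the numbers: the scenario's velocity profile is N(1.04, 0.51²)
truncated to [0.1, 4.0]; the estimators see only the 52 pedestrians that
ever had a free path and recover a mean slightly below the input (crowded
walkers are excluded, and movement is quantized to 0.53 m lattice steps).
The source–target row 0.68/0.32 is the realized draw of the configured
0.7/0.3 split for these 69 pedestrians. The fitness against an independent
replica is dominated by fifteen 1/ε = 10⁶ spikes — instants (mostly before
the train arrives and after the hall clears) where both runs agree exactly —
on top of ~17.7 from the crowded instants; higher is better, and
perturbed parameters score lower.

The same pipeline is available from the shell:

```bash
pedstream simulate examples/station_hall.yaml --seed 1 --out traj.csv
pedstream calibrate traj.csv regions.yaml --out calibration.yaml
pedstream validate traj.csv examples/station_hall.yaml --seeds 3
pedstream sensitivity examples/station_hall.yaml traj.csv --deviation 0.10
```

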