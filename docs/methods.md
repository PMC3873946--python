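# Methods

## The model

`pedstream` simulates pedestrian streams with a cellular automaton on a
hexagonal lattice. The hexagonal grid is preferred over a square one because
it offers two additional natural directions of movement, which reduces
lattice artifacts along diagonal paths. The lattice constant — the
center-to-center spacing of adjacent cells and the distance covered by one
move — defaults to 0.53 m, one body diameter of an average adult; it can be
lowered for, e.g., children. Each cell is, at any instant, empty or occupied
by exactly one person, an obstacle, a source, or a target.

Movement is potential-driven, with rules borrowed from electrostatics:

- **Target attraction (floor field).** Each target's long-range attraction
  is the arrival time of a wave front expanding at constant speed from the
  target cells through obstacle-free space. We compute it as the multi-source
  shortest-path distance on the hex adjacency graph (all edges weighted by
  the lattice constant), so descending the field takes an agent along a
  shortest obstacle-free lattice path. A continuous eikonal solver would
  reduce the residual lattice metric error further; the hexagonal
  neighborhood already keeps it small, and the graph formulation is exactly
  testable against an independent shortest-path oracle. Fields are static
  and recomputed only when topology changes; a dynamic variant that folds
  crowd clumps into the wave front is out of scope.
- **Repulsion.** Every pedestrian and every obstacle cell carries a radially
  symmetric repulsive potential `A * exp(-r / lambda)` with a hard cutoff,
  evaluated on Euclidean distances between cell centers. The exponential
  profile is monotone, "almost zero a few cells away", and has two
  interpretable parameters per term. All four repulsion parameters are
  calibration targets, not measured constants; the shipped fallbacks let the
  simulator run uncalibrated: agent amplitude 10 x floor-field weight (a
  contact never pays off against path gain), agent decay length half a cell,
  agent cutoff three lattice constants ("a few cells"), obstacle cutoff
  2.0 m — the empirically observed influence range of a wall.
- **Overall potential.** The per-cell sum of the weighted floor field, the
  repulsion of all *other* agents, and the summed repulsion of obstacle
  cells within the cutoff. Unreachable cells get `+inf`.

**Sequential update.** Time advances in global steps of `time_step`
(default 0.1 s, so that any speed up to 5.3 m/s needs at most one move per
step at the default lattice constant). Each step every agent accrues
distance credit `v * dt`; agents whose credit reaches one lattice constant
are *due* and attempt a move (the credit is debited per attempt), so faster
people are selected more often and on average walk at exactly their
free-flow speed while the path is free. Due agents act one at a time,
ordered by their lifetime in the simulation (oldest first by default; a
config switch flips the direction), which makes collisions structurally
impossible. A mover takes the free neighbor cell with the steepest descent
of the overall potential, provided it strictly improves on staying put;
equal minimizers are resolved uniformly from a seeded stream. The stay-put
rule prevents oscillation and is what turns blocking into slowing down.
Agents stepping onto a cell of their own target region are absorbed;
arrivals into a saturated source are queued and retried (with a warning
counter). The model is microscopic, discrete, and deterministic with
stochastic aspects — rule-based but potential-driven. Limited vision,
incomplete knowledge, group cohesion and multi-floor geometry are outside
the model.

**Free-flow speeds** are drawn from a normal distribution truncated by
rejection to `[lower, upper]` (defaults 0.1 and 4.0 m/s — below 0.1 m/s
dawdlers and loiterers are indistinguishable, above 4.0 m/s one is running).
A profile whose bounds keep less than 0.1% of the normal mass is rejected as
degenerate. Note the truncation shifts moments: e.g. a (1.04, 0.51) profile
truncated at 0.1 m/s has mean 1.078, not 1.04.

## Geometry conventions

Axial integer coordinates `(q, r)` with centers
`x = x_min + a (q + r/2)`, `y = y_min + a (sqrt(3)/2) r`; the six lattice
directions sit at 0-300 degrees in a fixed order used for all deterministic
tie-breaking. Only cells whose center lies inside the rectangular extent
exist; the boundary acts as an obstacle. Obstacles are rasterized by center
sampling (a cell is an obstacle iff its center lies strictly inside an
obstacle polygon) — deterministic and cheap; its known consequence is that
walls thinner than one lattice spacing may fail to seal, so configs should
use wall polygons at least one lattice constant thick. Point-to-cell lookup
is nearest-center (ties to the smaller cell index), which partitions the
extent exactly into clipped Voronoi cells.

## Calibration estimators

Inputs divide into stationary (topology, source/target positions),
quasi-stationary (velocity profile, density-flow relation, wall distances,
source-target matrix) and dynamic (arrival schedules) classes; the class
dictates how often a quantity must be re-estimated in deployment.

- **Free-flow speed extraction.** Per pedestrian, sliding windows (default
  2 s) of displacement/elapsed-time speed; a window counts as free-flow iff
  at its midpoint no other pedestrian is within `free_radius` (default
  2.0 m) in the *closed* forward half-plane of the walking direction —
  closed so that someone walking exactly abreast still blocks. One sample
  per pedestrian: the median of its qualifying windows. Windows without
  measurable displacement carry no direction and are skipped. Outlier
  filtering keeps samples in `[0.1, 4.0]` m/s; the profile fit is the sample
  mean and the n-1 standard deviation.
- **Normality check.** Cramer-von Mises `W^2` against the fitted normal,
  with the composite-null (estimated parameters) p-value from a parametric
  bootstrap (999 replicates; the statistic is location/scale invariant under
  re-estimation, so standard-normal replicates suffice). Default level 0.5%.
- **Source-target matrix / schedules.** A pedestrian's source is the region
  containing its first record, its target the region of its last; rows are
  normalized counts, pedestrians matching no region are counted as
  unassigned. Schedules bin first-record times (default 2 s bins).
- **Density-flow relation.** At each sample instant (default every 2 s):
  density = persons inside the measurement polygon / area; flow = density x
  mean instantaneous speed (central difference over 1 s), i.e. specific flow
  in persons/(m s). The scatter is smoothed by local-linear kernel
  regression with bandwidth 0.3 x the sampled density range; the quality
  band is the 90th percentile of absolute residuals.
- **Repulsion calibration.** Nelder-Mead over (agent amplitude, decay
  length) minimizing the mean squared deviation between the simulated
  density-flow samples (pooled over seeds) and the smooth reference curve;
  warm-startable, budgeted by objective evaluations.

## Validation and sensitivity

Tile densities: positions linearly interpolated between records, assigned to
half-open 1 m x 1 m tiles every 2 s. Fitness at an instant is
`1 / (epsilon + sum_k |rho_obs(k) - rho_sim(k)|)` with `epsilon = 1e-6`
persons/m^2 guarding exact matches; the overall fitness sums the per-instant
values. This aggregation weights near-perfect instants very heavily; an
alternative (one over the grand total deviation) is available behind a flag
but is not the default. The 6-s moving average is applied to density *maps
for reporting only*, never inside the fitness.

Sensitivity analysis scales one named input at a time by 1 +- deviation
(default 10%): velocity mean/sd, schedule counts (rounded half-up, events
rounding to zero are dropped), each source-target row (the leading
probability is scaled and the change spread proportionally over the other
targets, then renormalized), or a repulsion parameter. All cells — and the
unperturbed optimum — share one set of replicate seeds (common random
numbers), so a perturbation the scenario never uses scores exactly like the
optimum and comparisons are not drowned in seed noise. Perturbations that
produce an invalid scenario are reported infeasible rather than raised.

## Synthetic data

The fixture generator stands in for field trajectory data and always emits
the exact ground truth it used (per-agent speeds, targets, arrival times,
realized schedules). Two modes: *simulator* (full engine) and *kinematic* —
point agents moving in straight lines at their drawn speeds with no
exclusion or repulsion, assuming obstacle-free geometry between source and
target. Kinematic data is ideal for estimator tests because every recovered
quantity has an exact expected value; what it does not emulate is
congestion, evasion, lattice discretization or measurement noise, so
estimator tests passing on it demonstrate correctness of the estimators, not
robustness to real tracking artifacts (head-position jitter of up to ~9 cm,
hidden areas, distorted views).

Looped-corridor (fundamental diagram) experiments use a `recycle` option:
agents absorbed by a recycling target respawn as new agents (fresh id, same
speed) at a mapped source, keeping the corridor population — and hence
density — constant without periodic lattice topology.

## Problem sizes and seeds

A single master seed fans out via CRC-derived named substreams (spawning,
tie-breaks, fixtures, replicates), so components are independently
reproducible. The shipped example scenario is a 20 m x 12 m hall with 69
pedestrians over 180 s (a five-pulse train arrival plus a trickle of
background traffic), which one simulation covers in under a second; the
test suite's statistical checks use 10-50 seeds at this scale, a
2000-agent kinematic fixture for calibration recovery, and 200,000-draw
samples for the velocity sampler.

## Known limitations

- The inverse-L1 fitness is not a proper scoring rule against a single
  observed realization: its expectation is first-order flat in the model
  parameters at the truth, and below roughly one person/m^2 of typical tile
  occupancy it actually *increases* when the simulated population shrinks
  (unmatched persons cost less than matched ones are worth). Consequently a
  +-10% sensitivity screen against self-generated observed data ranks the
  true parameters first only at chance level; the score is informative when
  the observed data deviates systematically from the model (its original
  use), or with aggregation over much larger scenes.
- Greedy steepest descent plans one cell ahead; virtual pedestrians
  coordinate worse than real ones and local densities tend to be slightly
  overestimated — acceptable for a warning system, where underestimation
  would be the harmful direction.
- Center-sampling rasterization needs walls at least one lattice constant
  thick; source/target regions should contain at least one cell center.
- Speeds above `lattice_constant / time_step` (5.3 m/s at defaults) would
  need multiple moves per step; the engine supports it, but the potential
  landscape is only re-evaluated between attempts, not re-planned.
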