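# Demo railway-hall scenario: a train arrives at the platform (left edge),
# passengers disembark in pulses and cross the hall toward the east and south
# exits, skirting two food stalls; a trickle of other pedestrians enters from
# the south-west and heads east.  180 seconds are simulated.
duration: 180.0
extent: [0.0, 0.0, 20.0, 12.0]
lattice_constant: 0.53
time_step: 0.1
update_order: oldest_first
obstacles:
- [[8.0, 5.0], [10.0, 5.0], [10.0, 7.0], [8.0, 7.0]]
- [[13.0, 2.0], [15.0, 2.0], [15.0, 4.0], [13.0, 4.0]]
sources:
- id: platform
  region: [[0.3, 1.0], [1.6, 1.0], [1.6, 11.0], [0.3, 11.0]]
  schedule: [[5.0, 12], [7.0, 12], [9.0, 12], [11.0, 12], [13.0, 12]]
- id: hall_entry
  region: [[3.5, 0.3], [5.0, 0.3], [5.0, 1.1], [3.5, 1.1]]
  schedule: [[0.0, 1], [20.0, 1], [40.0, 1], [60.0, 1], [80.0, 1], [100.0, 1],
             [120.0, 1], [140.0, 1], [160.0, 1]]
targets:
- id: exit_east
  region: [[19.2, 4.0], [19.8, 4.0], [19.8, 8.0], [19.2, 8.0]]
- id: exit_south
  region: [[6.0, 0.2], [9.0, 0.2], [9.0, 0.8], [6.0, 0.8]]
source_target_matrix:
  platform: {exit_east: 0.7, exit_south: 0.3}
  hall_entry: {exit_east: 1.0}
velocity_profile: {mean: 1.04, sd: 0.51, lower: 0.1, upper: 4.0}
potential_params:
  agent_amplitude: 10.0
  agent_range: 0.265
  agent_cutoff: 1.59
  obstacle_amplitude: 5.0
  obstacle_range: 0.5
  obstacle_cutoff: 2.0
  floorfield_weight: 1.0
recycle: {}
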