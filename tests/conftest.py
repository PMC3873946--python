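"""Shared builders for test scenarios (all fixtures are generated in memory)."""

from __future__ import annotations

from pathlib import Path

import pytest
from shapely.geometry import box

from pedstream.engine import Scenario, Schedule, SourceSpec, TargetSpec, VelocityProfile
from pedstream.potentials import PotentialParams

EXAMPLES = Path(__file__).resolve().parent.parent / "examples"


def corridor_scenario(
    length: float = 22.0,
    width: float = 3.0,
    speed_mean: float = 1.0,
    speed_sd: float = 0.0,
    schedule: tuple = ((0.0, 1),),
    duration: float = 60.0,
    **kwargs,
) -> Scenario:
    """Straight corridor: source strip at the left end, target strip at the right."""
    return Scenario(
        extent=(0.0, 0.0, length, width),
        sources=[SourceSpec("in", box(0.2, 0.2, 1.5, width - 0.2), Schedule(events=schedule))],
        targets=[TargetSpec("out", box(length - 1.5, 0.2, length - 0.2, width - 0.2))],
        source_target_matrix={"in": {"out": 1.0}},
        velocity_profile=VelocityProfile(mean=speed_mean, sd=speed_sd),
        duration=duration,
        **kwargs,
    )


def looped_corridor_scenario(
    n_agents: int,
    length: float = 20.0,
    width: float = 2.0,
    duration: float = 80.0,
    speed_mean: float = 1.34,
    speed_sd: float = 0.26,
) -> Scenario:
    """Closed circuit: the whole corridor is the initial source; walkers who
    reach the right-end target respawn at the left end, so the agent count —
    and with it the density — stays constant."""
    return Scenario(
        extent=(0.0, 0.0, length, width),
        sources=[
            SourceSpec("fill", box(0.1, 0.1, length - 2.0, width - 0.1), Schedule(events=((0.0, n_agents),))),
            SourceSpec("inlet", box(0.1, 0.1, 1.2, width - 0.1), Schedule(events=())),
        ],
        targets=[TargetSpec("end", box(length - 1.0, 0.1, length - 0.1, width - 0.1))],
        source_target_matrix={"fill": {"end": 1.0}, "inlet": {"end": 1.0}},
        velocity_profile=VelocityProfile(mean=speed_mean, sd=speed_sd),
        duration=duration,
        recycle={"end": "inlet"},
    )


def pulse_scenario(
    n_pulse: int = 30,
    duration: float = 60.0,
    speed_mean: float = 1.04,
    speed_sd: float = 0.51,
    split: float = 0.7,
) -> Scenario:
    """Small arrival-pulse hall: one platform source, two exits, one stall."""
    return Scenario(
        extent=(0.0, 0.0, 16.0, 8.0),
        obstacles=[box(7.0, 3.0, 9.0, 5.0)],
        sources=[
            SourceSpec(
                "platform",
                box(0.3, 0.8, 1.6, 7.2),
                Schedule(events=((2.0, n_pulse // 2), (4.0, n_pulse - n_pulse // 2))),
            )
        ],
        targets=[
            TargetSpec("exit_east", box(15.2, 2.5, 15.8, 5.5)),
            TargetSpec("exit_south", box(4.0, 0.2, 7.0, 0.7)),
        ],
        source_target_matrix={"platform": {"exit_east": split, "exit_south": 1.0 - split}},
        velocity_profile=VelocityProfile(mean=speed_mean, sd=speed_sd),
        duration=duration,
    )


@pytest.fixture(scope="session")
def demo_scenario():
    from pedstream.scenario_io import load_scenario

    return load_scenario(EXAMPLES / "station_hall.yaml")
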