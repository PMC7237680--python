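import numpy as np
import pytest

from blinkengage.synth import CohortParams, simulate_cohort
from blinkengage.types import BlinkEvent, Scene, SceneSchedule


@pytest.fixture(scope="session")
def default_cohort():
    """Full-size simulated cohort (11 land / 10 water counters, rho=0.5)."""
    records, schedules, profiles = simulate_cohort(CohortParams(seed=42))
    return records, schedules, profiles


@pytest.fixture(scope="session")
def small_cohort():
    """Small, fast cohort (4/4, two videos) for classifier plumbing tests."""
    params = CohortParams(n_land=4, n_water=4, seed=7)
    records, schedules, profiles = simulate_cohort(
        params, target_duration_s=120.0, conditions=(5.0, 10.0)
    )
    return records, schedules, profiles


def two_scene_schedule(condition_s=60.0, first="land", video_id="v"):
    other = "water" if first == "land" else "land"
    return SceneSchedule(
        video_id=video_id,
        condition_s=condition_s,
        scenes=[
            Scene(1, first, 0.0, condition_s),
            Scene(2, other, condition_s, 2 * condition_s),
        ],
    )


def make_events(onsets, duration=0.2):
    return [BlinkEvent(float(t), duration) for t in onsets]
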