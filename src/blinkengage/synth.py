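"""Synthetic cohorts, schedules, blink streams, and pupil traces.

The generator emulates the blink statistics of a two-task viewing study:

* a cohort of ``n_land + n_water`` adults split into land counters and water
  counters, with baseline blink rates whose *observed* distribution has mean
  12.6 blinks/minute, SD 6.7 bpm, and range 2-26 bpm;
* 13 composite videos per participant, alternating two scene categories at a
  constant per-video rate of 1, 5, 10, ..., 60 s;
* task-locked blink suppression: each participant's blink intensity is
  ``lambda * rho`` during task-relevant scenes and ``lambda * (2 - rho)``
  during task-irrelevant scenes, so the session-mean rate stays at ``lambda``
  for any suppression ratio ``rho``;
* blinks as a dead-time-modified Poisson process (no blink can start while
  another is in progress), with durations uniform on 150-400 ms.

Because a blink occupies time, naive Poisson generation at the target rate
would undershoot it.  The generator therefore uses the compensated intensity
``lambda_gen = r / (1 - r * mean_duration)`` (rates in events/second), which
makes the long-run *realized* rate equal the target exactly for a renewal
process with exponential waits and random dead times (Wald's identity), and
keeps closed-form oracles available for the tests.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats

from .types import (
    CATEGORY_LAND,
    CATEGORY_WATER,
    CONDITIONS_S,
    GROUP_LAND,
    GROUP_WATER,
    BlinkEvent,
    ParticipantRecord,
    PupilTrace,
    Scene,
    SceneSchedule,
    ValidationError,
    expected_parity,
    relevant_category,
)

logger = logging.getLogger(__name__)

DEFAULT_TARGET_DURATION_S = 160.0


@dataclass(frozen=True)
class CohortParams:
    """Calibration of the synthetic cohort.

    ``rate_mean_bpm``/``rate_sd_bpm``/``rate_bounds_bpm`` describe the
    *realized* (truncated) baseline-rate distribution; the generator solves
    for the parent normal whose truncation reproduces them.  ``suppression_rho``
    is the ratio of task-relevant to baseline blink rate; 1 means no effect.
    """

    n_land: int = 11
    n_water: int = 10
    rate_mean_bpm: float = 12.6
    rate_sd_bpm: float = 6.7
    rate_bounds_bpm: Tuple[float, float] = (2.0, 26.0)
    suppression_rho: float = 0.5
    rho_jitter_sd: float = 0.0
    blink_dur_range_s: Tuple[float, float] = (0.150, 0.400)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_land + self.n_water < 2:
            raise ValidationError("cohort needs at least 2 participants")
        if not (0 < self.suppression_rho <= 1):
            raise ValidationError("suppression_rho must be in (0, 1]")
        if not self.rate_bounds_bpm[0] > 0:
            raise ValidationError("lower rate bound must be positive")
        if not (0 < self.blink_dur_range_s[0] <= self.blink_dur_range_s[1]):
            raise ValidationError("invalid blink duration range")

    @property
    def mean_blink_duration_s(self) -> float:
        return 0.5 * (self.blink_dur_range_s[0] + self.blink_dur_range_s[1])


@dataclass(frozen=True)
class ParticipantProfile:
    """Latent per-participant parameters behind the simulated blink stream."""

    participant_id: str
    group: str
    parity: str
    lambda_bpm: float
    rho: float
    blink_dur_range_s: Tuple[float, float] = (0.150, 0.400)

    def __post_init__(self) -> None:
        if not (0 < self.rho <= 1):
            raise ValidationError(
                f"{self.participant_id}: rho must be in (0, 1], got {self.rho}"
            )

    @property
    def first_category(self) -> str:
        """First-scene category of this participant's stimulus set.

        Follows the counterbalancing convention: task-relevant scenes occupy
        odd positions iff the first scene shows the relevant category.
        """
        rel = relevant_category(self.group)
        other = CATEGORY_WATER if rel == CATEGORY_LAND else CATEGORY_LAND
        return rel if self.parity == "attended_odd" else other


# ---------------------------------------------------------------------------
# Schedules


def make_schedules(
    target_duration_s: float = DEFAULT_TARGET_DURATION_S,
    conditions: Sequence[float] = CONDITIONS_S,
    first_category: str = CATEGORY_LAND,
) -> List[SceneSchedule]:
    """Build one alternating schedule per condition.

    Scene count is the largest even integer ``n`` with
    ``n * condition_s <= target_duration_s`` (even so that both categories get
    equal exposure), minimum 2.  With the default 160 s target every video
    lands inside the study's 90-160.2 s envelope.
    """
    if not conditions:
        raise ValidationError("conditions must be nonempty")
    if first_category not in (CATEGORY_LAND, CATEGORY_WATER):
        raise ValidationError(f"unknown category {first_category!r}")
    other = CATEGORY_WATER if first_category == CATEGORY_LAND else CATEGORY_LAND

    schedules = []
    for cond in conditions:
        n = int(math.floor(target_duration_s / cond + 1e-9))
        n -= n % 2
        if n < 2:
            raise ValidationError(
                f"condition {cond} s cannot fit two scenes in "
                f"{target_duration_s} s"
            )
        scenes = [
            Scene(
                index=i + 1,
                category=first_category if i % 2 == 0 else other,
                onset_s=i * float(cond),
                offset_s=(i + 1) * float(cond),
            )
            for i in range(n)
        ]
        schedules.append(
            SceneSchedule(
                video_id=f"v{int(cond):02d}_{first_category}",
                condition_s=float(cond),
                scenes=scenes,
            )
        )
    return schedules


def make_schedule_sets(
    target_duration_s: float = DEFAULT_TARGET_DURATION_S,
    conditions: Sequence[float] = CONDITIONS_S,
) -> Dict[str, SceneSchedule]:
    """Both counterbalanced stimulus sets (land-first and water-first), keyed
    by video_id."""
    out: Dict[str, SceneSchedule] = {}
    for cat in (CATEGORY_LAND, CATEGORY_WATER):
        for sched in make_schedules(target_duration_s, conditions, cat):
            out[sched.video_id] = sched
    return out


def schedules_for_profile(
    profile: ParticipantProfile, schedules: Dict[str, SceneSchedule]
) -> List[SceneSchedule]:
    """The stimulus set a participant watches, sorted by condition."""
    wanted = [
        s for s in schedules.values() if s.first_category == profile.first_category
    ]
    return sorted(wanted, key=lambda s: s.condition_s)


# ---------------------------------------------------------------------------
# Baseline-rate calibration


def calibrate_truncated_normal(
    mean: float, sd: float, bounds: Tuple[float, float]
) -> Tuple[float, float]:
    """Parent (mu, sigma) of a normal whose truncation to ``bounds`` has the
    requested mean and SD.

    The printed cohort statistics describe rates that live inside the bounds,
    so they are moments of the truncated law, not of the parent.  Raises if no
    parent can reach them (the truncated SD is capped by the uniform limit
    ``(hi - lo) / sqrt(12)``).
    """
    lo, hi = bounds
    if not lo < mean < hi:
        raise ValidationError(
            f"target mean {mean} outside truncation bounds [{lo}, {hi}]"
        )
    sd_cap = (hi - lo) / math.sqrt(12.0)
    if not 0 < sd < sd_cap * 0.999:
        raise ValidationError(
            f"target SD {sd} infeasible for bounds [{lo}, {hi}] "
            f"(must be in (0, {sd_cap:.3f}))"
        )

    def moments(mu: float, sigma: float) -> Tuple[float, float]:
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        d = stats.truncnorm(a, b, loc=mu, scale=sigma)
        return float(d.mean()), float(d.std())

    def resid(p: np.ndarray) -> List[float]:
        m, s = moments(p[0], math.exp(p[1]))
        return [m - mean, s - sd]

    sol, info, ier, msg = optimize.fsolve(
        resid, [mean, math.log(sd)], full_output=True
    )
    if ier != 1:
        raise ValidationError(f"truncated-normal calibration failed: {msg}")
    return float(sol[0]), float(math.exp(sol[1]))


def sample_cohort(params: CohortParams) -> List[ParticipantProfile]:
    """Draw a cohort of participant profiles, reproducible from the seed.

    Groups are assigned n_land/n_water; the first-scene category is
    counterbalanced within each group, which fixes the parity labels.
    """
    n = params.n_land + params.n_water
    rng = np.random.default_rng(params.seed)
    lo, hi = params.rate_bounds_bpm

    if params.rate_sd_bpm == 0:
        rates = np.full(n, params.rate_mean_bpm)
    else:
        mu, sigma = calibrate_truncated_normal(
            params.rate_mean_bpm, params.rate_sd_bpm, params.rate_bounds_bpm
        )
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        rates = stats.truncnorm(a, b, loc=mu, scale=sigma).rvs(n, random_state=rng)

    if params.rho_jitter_sd > 0:
        rhos = np.clip(
            rng.normal(params.suppression_rho, params.rho_jitter_sd, n), 1e-6, 1.0
        )
    else:
        rhos = np.full(n, params.suppression_rho)

    profiles = []
    groups = [GROUP_LAND] * params.n_land + [GROUP_WATER] * params.n_water
    index_in_group = {GROUP_LAND: 0, GROUP_WATER: 0}
    for i, group in enumerate(groups):
        k = index_in_group[group]
        index_in_group[group] += 1
        rel = relevant_category(group)
        other = CATEGORY_WATER if rel == CATEGORY_LAND else CATEGORY_LAND
        first = rel if k % 2 == 0 else other  # counterbalance within group
        profiles.append(
            ParticipantProfile(
                participant_id=f"P{i + 1:02d}",
                group=group,
                parity=expected_parity(group, first),
                lambda_bpm=float(rates[i]),
                rho=float(rhos[i]),
                blink_dur_range_s=params.blink_dur_range_s,
            )
        )
    return profiles


# ---------------------------------------------------------------------------
# Blink-stream simulation


def _generation_rates_per_s(
    profile: ParticipantProfile, schedule: SceneSchedule
) -> np.ndarray:
    """Dead-time-compensated generation intensity per scene, events/second."""
    rel = relevant_category(profile.group)
    lam = profile.lambda_bpm / 60.0
    d_mean = 0.5 * (profile.blink_dur_range_s[0] + profile.blink_dur_range_s[1])
    rates = np.empty(len(schedule.scenes))
    for i, sc in enumerate(schedule.scenes):
        r = lam * profile.rho if sc.category == rel else lam * (2.0 - profile.rho)
        if r * d_mean >= 1.0:
            raise ValidationError(
                f"target rate {r * 60:.1f} bpm too high for dead-time "
                "compensation"
            )
        rates[i] = r / (1.0 - r * d_mean) if r > 0 else 0.0
    return rates


def simulate_blinks(
    profile: ParticipantProfile,
    schedule: SceneSchedule,
    seed_or_rng,
) -> List[BlinkEvent]:
    """Simulate one participant-video blink stream.

    Events come from a piecewise-constant-intensity Poisson process with dead
    time equal to each blink's duration; the generation intensity is
    compensated so the realized per-category rates match the targets
    ``lambda*rho`` (relevant scenes) and ``lambda*(2-rho)`` (irrelevant).
    """
    rng = np.random.default_rng(seed_or_rng) if not isinstance(
        seed_or_rng, np.random.Generator
    ) else seed_or_rng

    scenes = [sc for sc in schedule.scenes if sc.duration_s > 0]
    if not scenes:
        return []
    edges = np.array([sc.onset_s for sc in scenes] + [scenes[-1].offset_s])
    rates = _generation_rates_per_s(profile, schedule)
    # cumulative integral of the generation intensity at the scene edges
    cum = np.concatenate([[0.0], np.cumsum(rates * np.diff(edges))])
    total_mass = cum[-1]
    t_end = edges[-1]

    def inv_cum(u: float) -> float:
        """Time at which the cumulative intensity reaches u."""
        j = int(np.searchsorted(cum, u, side="right")) - 1
        j = min(j, len(rates) - 1)
        if rates[j] <= 0:
            return math.inf
        return edges[j] + (u - cum[j]) / rates[j]

    def cum_at(t: float) -> float:
        j = int(np.searchsorted(edges, t, side="right")) - 1
        j = min(max(j, 0), len(rates) - 1)
        return cum[j] + rates[j] * (t - edges[j])

    lo_d, hi_d = profile.blink_dur_range_s
    events: List[BlinkEvent] = []
    t = edges[0]
    while True:
        u = cum_at(t) + rng.exponential()
        if u >= total_mass:
            break
        onset = inv_cum(u)
        if onset >= t_end:
            break
        duration = rng.uniform(lo_d, hi_d)
        events.append(BlinkEvent(onset_s=float(onset), duration_s=float(duration)))
        t = onset + duration
        if t >= t_end:
            break
    return events


def simulate_cohort(
    params: CohortParams,
    schedules: Optional[Dict[str, SceneSchedule]] = None,
    target_duration_s: float = DEFAULT_TARGET_DURATION_S,
    conditions: Sequence[float] = CONDITIONS_S,
) -> Tuple[List[ParticipantRecord], Dict[str, SceneSchedule], List[ParticipantProfile]]:
    """Sample a cohort and simulate every participant-video blink stream.

    Returns records (events attached), the schedule table covering both
    counterbalanced stimulus sets, and the latent profiles.  Per-stream seeds
    are spawned deterministically from ``params.seed``.
    """
    if schedules is None:
        schedules = make_schedule_sets(target_duration_s, conditions)
    profiles = sample_cohort(params)
    root = np.random.SeedSequence(params.seed)
    streams = root.spawn(len(profiles))
    records = []
    for profile, ss in zip(profiles, streams):
        my_videos = schedules_for_profile(profile, schedules)
        video_rngs = [np.random.default_rng(s) for s in ss.spawn(len(my_videos))]
        events = {
            sched.video_id: simulate_blinks(profile, sched, rng)
            for sched, rng in zip(my_videos, video_rngs)
        }
        records.append(
            ParticipantRecord(
                participant_id=profile.participant_id,
                group=profile.group,
                parity=profile.parity,
                events=events,
                session_duration_s=sum(s.duration_s for s in my_videos),
            )
        )
    return records, schedules, profiles


# ---------------------------------------------------------------------------
# Pupil-trace rendering (inverse of the blink detector)

TRACE_BASELINE_DIAMETER = 100.0  # arbitrary device units
TRACE_BASELINE_CENTER_Y = 240.0  # pixels
TRACE_BLINK_CENTER_DROP = 40.0  # downward deflection at full occlusion, pixels
RAMP_FRACTION = 0.25  # fraction of blink duration spent on each lid ramp


def blink_occlusion_profile(
    rel_t: np.ndarray, duration_s: float, ramp_fraction: float = RAMP_FRACTION
) -> np.ndarray:
    """Fraction of the pupil visible at time ``rel_t`` after blink onset.

    Trapezoidal lid model: linear close over ``ramp_fraction * duration``,
    full occlusion, then a symmetric linear reopen.
    """
    ramp = ramp_fraction * duration_s
    vis = np.ones_like(rel_t)
    closing = (rel_t >= 0) & (rel_t < ramp)
    closed = (rel_t >= ramp) & (rel_t <= duration_s - ramp)
    opening = (rel_t > duration_s - ramp) & (rel_t <= duration_s)
    vis[closing] = 1.0 - rel_t[closing] / ramp
    vis[closed] = 0.0
    vis[opening] = (rel_t[opening] - (duration_s - ramp)) / ramp
    return vis


def render_pupil_trace(
    events: Sequence[BlinkEvent],
    duration_s: float,
    sample_rate_hz: float = 60.0,
    noise_sd: float = 0.0,
    seed_or_rng=0,
) -> PupilTrace:
    """Render a pupil trace with blink occlusions.

    Diameter ramps to 0 and back over each blink's duration; the measured
    pupil center deflects downward as the lid closes; ``valid`` is False while
    the pupil is fully occluded.  Gaussian measurement noise (SD ``noise_sd``
    in diameter units, same magnitude in pixels for center_y) is added to
    valid samples only.
    """
    rng = np.random.default_rng(seed_or_rng) if not isinstance(
        seed_or_rng, np.random.Generator
    ) else seed_or_rng
    n = int(round(duration_s * sample_rate_hz))
    t = np.arange(n) / sample_rate_hz
    vis = np.ones(n)
    for ev in events:
        if ev.onset_s < 0 or ev.onset_s > duration_s:
            raise ValidationError(f"event at t={ev.onset_s} outside trace")
        if ev.offset_s > duration_s:
            logger.warning(
                "blink at t=%.3f extends past trace end; truncated", ev.onset_s
            )
        sel = (t >= ev.onset_s) & (t <= min(ev.offset_s, duration_s))
        vis[sel] = np.minimum(
            vis[sel], blink_occlusion_profile(t[sel] - ev.onset_s, ev.duration_s)
        )
    valid = vis > 0
    diameter = TRACE_BASELINE_DIAMETER * vis
    center_y = TRACE_BASELINE_CENTER_Y - TRACE_BLINK_CENTER_DROP * (1.0 - vis)
    if noise_sd > 0:
        diameter = diameter + np.where(valid, rng.normal(0, noise_sd, n), 0.0)
        center_y = center_y + np.where(valid, rng.normal(0, noise_sd, n), 0.0)
        diameter = np.maximum(diameter, 0.0)
    diameter[~valid] = 0.0
    return PupilTrace(
        sample_rate_hz=sample_rate_hz,
        t=t,
        diameter=diameter,
        center_y=center_y,
        valid=valid,
    )
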