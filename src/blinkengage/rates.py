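"""Blink-rate summaries: BPM over windows, per-scene-category rates, interval
feature vectors, and smoothed instantaneous group rate.

All rates are blinks per minute (bpm).  A blink belongs to a window iff its
*onset* falls inside the half-open window ``[start, end)``.  Category rates
pool counts over exposure (total blinks / total seconds in the category)
rather than averaging per-scene rates — essential for 1 s scenes, where
per-scene counts are almost all zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .types import (
    CATEGORY_LAND,
    CATEGORY_WATER,
    BlinkEvent,
    ParticipantRecord,
    RateProfile,
    SceneSchedule,
    ValidationError,
    relevant_category,
)

Window = Tuple[float, float]


def count_in_windows(events: Sequence[BlinkEvent], windows: Sequence[Window]) -> int:
    """Number of events whose onset lies in any half-open window."""
    if not events:
        return 0
    onsets = np.array([e.onset_s for e in events])
    total = 0
    for start, end in windows:
        total += int(np.count_nonzero((onsets >= start) & (onsets < end)))
    return total


def bpm(events: Sequence[BlinkEvent], windows: Sequence[Window]) -> float:
    """Mean blinks/minute over a set of disjoint windows (pooled, not
    averaged per window)."""
    exposure = sum(end - start for start, end in windows)
    if exposure <= 0:
        raise ValidationError("zero exposure: cannot compute a rate")
    starts = sorted(windows)
    for (s1, e1), (s2, _) in zip(starts, starts[1:]):
        if s2 < e1 - 1e-12:
            raise ValidationError("windows must be disjoint")
    return 60.0 * count_in_windows(events, windows) / exposure


@dataclass
class SceneRates:
    """Per-participant category blink rates, pooled across videos.

    ``bpm_relevant``/``bpm_irrelevant`` relabel land/water by the
    participant's task group.  ``by_condition`` holds the same quantities
    restricted to each scene-duration condition.
    """

    participant_id: str
    group: str
    bpm_land: float
    bpm_water: float
    bpm_relevant: float
    bpm_irrelevant: float
    bpm_session: float
    by_condition: Dict[float, "SceneRates"] = field(default_factory=dict)

    @property
    def metric(self) -> float:
        """Content-aware classification metric: land minus water bpm."""
        return self.bpm_land - self.bpm_water


def _pooled_rates(
    record: ParticipantRecord,
    videos: Sequence[SceneSchedule],
) -> Tuple[float, float, float]:
    """(bpm_land, bpm_water, bpm_session) pooled over the given videos."""
    counts = {CATEGORY_LAND: 0, CATEGORY_WATER: 0}
    exposure = {CATEGORY_LAND: 0.0, CATEGORY_WATER: 0.0}
    for sched in videos:
        events = record.events.get(sched.video_id, [])
        for cat in (CATEGORY_LAND, CATEGORY_WATER):
            wins = sched.windows(cat)
            counts[cat] += count_in_windows(events, wins)
            exposure[cat] += sum(e - s for s, e in wins)
    total_exposure = exposure[CATEGORY_LAND] + exposure[CATEGORY_WATER]
    if total_exposure <= 0:
        raise ValidationError(
            f"participant {record.participant_id}: zero exposure"
        )
    out = {}
    for cat in (CATEGORY_LAND, CATEGORY_WATER):
        if exposure[cat] <= 0:
            raise ValidationError(
                f"participant {record.participant_id}: zero {cat} exposure"
            )
        out[cat] = 60.0 * counts[cat] / exposure[cat]
    session = 60.0 * (counts[CATEGORY_LAND] + counts[CATEGORY_WATER]) / total_exposure
    return out[CATEGORY_LAND], out[CATEGORY_WATER], session


def scene_rates(
    record: ParticipantRecord, schedules: Mapping[str, SceneSchedule]
) -> SceneRates:
    """Category and session rates for one participant, pooled across all
    watched videos, plus per-condition variants."""
    videos = []
    for vid in sorted(record.events):
        if vid not in schedules:
            raise ValidationError(
                f"participant {record.participant_id}: no schedule for video {vid!r}"
            )
        videos.append(schedules[vid])
    if not videos:
        raise ValidationError(f"participant {record.participant_id}: no videos")

    def build(videos_subset: Sequence[SceneSchedule]) -> SceneRates:
        land, water, session = _pooled_rates(record, videos_subset)
        rel = relevant_category(record.group)
        relevant, irrelevant = (land, water) if rel == CATEGORY_LAND else (water, land)
        return SceneRates(
            participant_id=record.participant_id,
            group=record.group,
            bpm_land=land,
            bpm_water=water,
            bpm_relevant=relevant,
            bpm_irrelevant=irrelevant,
            bpm_session=session,
        )

    result = build(videos)
    for sched in videos:
        result.by_condition[sched.condition_s] = build([sched])
    return result


def interval_vector(
    record: ParticipantRecord,
    schedules: Mapping[str, SceneSchedule],
    interval_s: float,
) -> RateProfile:
    """Concatenated per-interval blink rates, the content-unaware feature.

    Per video: consecutive ``[k*interval, (k+1)*interval)`` bins from video
    onset, trailing partial bin dropped; videos concatenated in condition
    order.  Values in bpm.
    """
    if interval_s <= 0:
        raise ValidationError("interval_s must be positive")
    videos = sorted(
        (schedules[vid] for vid in record.events),
        key=lambda s: (s.condition_s, s.video_id),
    )
    chunks = []
    for sched in videos:
        n_bins = int(np.floor(sched.duration_s / interval_s + 1e-9))
        if n_bins == 0:
            continue
        edges = sched.onset_s + interval_s * np.arange(n_bins + 1)
        onsets = np.array([e.onset_s for e in record.events[sched.video_id]])
        if len(onsets):
            # np.histogram's last bin is closed; a blink exactly at the final
            # edge belongs to the dropped partial bin under the half-open rule
            counts, _ = np.histogram(onsets[onsets < edges[-1]], bins=edges)
        else:
            counts = np.zeros(n_bins)
        chunks.append(60.0 * counts / interval_s)
    values = np.concatenate(chunks) if chunks else np.empty(0)
    return RateProfile(
        participant_id=record.participant_id, interval_s=interval_s, values=values
    )


def instantaneous_rate(
    event_sets: Sequence[Sequence[BlinkEvent]],
    duration_s: float,
    bandwidth_s: float = 1.0,
    sample_rate_hz: float = 30.0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Smoothed group blink rate over video time.

    Per-frame blink-onset counts are averaged across participants, convolved
    with a Gaussian kernel (SD ``bandwidth_s``), and scaled to blinks/minute.
    Kernel mass lost at the trace edges is renormalized, so the time integral
    of the rate conserves the mean blink count.

    Returns ``(t, rate_bpm)``.
    """
    if bandwidth_s <= 0:
        raise ValidationError("bandwidth_s must be > 0")
    n = int(round(duration_s * sample_rate_hz))
    t = np.arange(n) / sample_rate_hz
    counts = np.zeros(n)
    for events in event_sets:
        for ev in events:
            idx = int(np.floor(ev.onset_s * sample_rate_hz))
            if 0 <= idx < n:
                counts[idx] += 1.0
    counts /= max(len(event_sets), 1)

    half = int(np.ceil(4 * bandwidth_s * sample_rate_hz))
    k = np.arange(-half, half + 1) / sample_rate_hz
    kernel = np.exp(-0.5 * (k / bandwidth_s) ** 2)
    kernel /= kernel.sum()
    smoothed = np.convolve(counts, kernel, mode="same")
    # renormalize for truncated kernel mass at the edges
    mass = np.convolve(np.ones(n), kernel, mode="same")
    smoothed /= mass
    rate_bpm = smoothed * sample_rate_hz * 60.0
    return t, rate_bpm
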