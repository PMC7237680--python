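"""Shared domain types for the blink-rate engagement pipeline.

The study design these types describe: participants watch composite videos
that alternate between two scene categories ("land" and "water") at a fixed
per-video rate, while counting animals of one category.  Blinks are point
events on the video timeline; engagement shows up as a *suppression* of
blinking during scenes relevant to the participant's counting task.

Time convention: seconds from the onset of each composite video's alternating
scene content.  Instruction and response screens are outside analysis time.
Scene intervals are half-open ``[onset, offset)``; an event whose onset falls
exactly on a boundary belongs to the later scene.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

CATEGORY_LAND = "land"
CATEGORY_WATER = "water"
CATEGORIES = (CATEGORY_LAND, CATEGORY_WATER)

GROUP_LAND = "land_counter"
GROUP_WATER = "water_counter"
GROUPS = (GROUP_LAND, GROUP_WATER)

PARITY_ODD = "attended_odd"
PARITY_EVEN = "attended_even"
PARITIES = (PARITY_ODD, PARITY_EVEN)

#: Scene-alternation conditions used in the study design, in seconds.
CONDITIONS_S = (1, 5, 10, 15, 20, 25, 30, 35, 40, 45, 50, 55, 60)

#: Composite-video duration envelope in seconds (1.5 to 2.67 minutes).
VIDEO_DURATION_BOUNDS_S = (90.0, 160.2)


class ValidationError(ValueError):
    """An object violates a domain invariant."""


class ParseError(ValueError):
    """A file cannot be parsed into domain objects."""


def relevant_category(group: str) -> str:
    """Scene category that is task-relevant for a group of counters."""
    if group == GROUP_LAND:
        return CATEGORY_LAND
    if group == GROUP_WATER:
        return CATEGORY_WATER
    raise ValidationError(f"unknown group label: {group!r}")


def expected_parity(group: str, first_category: str) -> str:
    """Parity label implied by group and the first scene's category.

    Task-relevant scenes occupy odd positions exactly when the first scene
    is the relevant category.
    """
    return PARITY_ODD if relevant_category(group) == first_category else PARITY_EVEN


@dataclass(frozen=True)
class Scene:
    index: int  # 1-based position within the video
    category: str
    onset_s: float
    offset_s: float

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


@dataclass
class SceneSchedule:
    """Alternation timeline of one composite video.

    Scenes are strictly contiguous, strictly alternate between the two
    categories, and all share the video's scene duration ``condition_s``.
    """

    video_id: str
    condition_s: float
    scenes: List[Scene]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.scenes:
            raise ValidationError(f"schedule {self.video_id}: no scenes")
        tol = 1e-9
        for i, sc in enumerate(self.scenes):
            if sc.index != i + 1:
                raise ValidationError(
                    f"schedule {self.video_id}: scene indices must be 1-based "
                    f"and consecutive (got {sc.index} at position {i})"
                )
            if sc.category not in CATEGORIES:
                raise ValidationError(
                    f"schedule {self.video_id}: unknown category {sc.category!r}"
                )
            if abs(sc.duration_s - self.condition_s) > tol:
                raise ValidationError(
                    f"schedule {self.video_id}: scene {sc.index} duration "
                    f"{sc.duration_s} != condition {self.condition_s}"
                )
            if i > 0:
                prev = self.scenes[i - 1]
                if abs(prev.offset_s - sc.onset_s) > tol:
                    raise ValidationError(
                        f"schedule {self.video_id}: scenes {prev.index} and "
                        f"{sc.index} are not contiguous"
                    )
                if prev.category == sc.category:
                    raise ValidationError(
                        f"schedule {self.video_id}: scenes {prev.index} and "
                        f"{sc.index} do not alternate"
                    )

    def validate_duration_envelope(self) -> None:
        """Enforce the study's composite-video length envelope.

        Applied at the file-I/O and generator boundary so that short unit
        fixtures remain constructible.
        """
        lo, hi = VIDEO_DURATION_BOUNDS_S
        if not (lo - 1e-9 <= self.duration_s <= hi + 1e-9):
            raise ValidationError(
                f"schedule {self.video_id}: duration {self.duration_s:.3f} s "
                f"outside [{lo}, {hi}] s"
            )

    @property
    def onset_s(self) -> float:
        return self.scenes[0].onset_s

    @property
    def offset_s(self) -> float:
        return self.scenes[-1].offset_s

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s

    @property
    def first_category(self) -> str:
        return self.scenes[0].category

    def windows(self, category: str) -> List[Tuple[float, float]]:
        """Half-open [onset, offset) windows of one scene category."""
        if category not in CATEGORIES:
            raise ValidationError(f"unknown category {category!r}")
        return [
            (sc.onset_s, sc.offset_s) for sc in self.scenes if sc.category == category
        ]


@dataclass(frozen=True, order=True)
class BlinkEvent:
    """One blink anchored to video time."""

    onset_s: float
    duration_s: float

    def __post_init__(self) -> None:
        if not self.duration_s > 0:
            raise ValidationError(
                f"blink at t={self.onset_s}: duration must be > 0, "
                f"got {self.duration_s}"
            )

    @property
    def offset_s(self) -> float:
        return self.onset_s + self.duration_s


def validate_event_list(events: Sequence[BlinkEvent], context: str = "") -> None:
    """Check that events are sorted by onset and non-overlapping."""
    where = f" ({context})" if context else ""
    for a, b in zip(events, events[1:]):
        if b.onset_s < a.onset_s:
            raise ValidationError(f"events not sorted by onset{where}")
        if b.onset_s < a.offset_s - 1e-12:
            raise ValidationError(
                f"overlapping blinks at t={a.onset_s} and t={b.onset_s}{where}"
            )


@dataclass
class ParticipantRecord:
    """One participant's labels and per-video blink events."""

    participant_id: str
    group: str
    parity: str
    events: Dict[str, List[BlinkEvent]] = field(default_factory=dict)
    session_duration_s: Optional[float] = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ParseError(
                f"participant {self.participant_id}: unknown group {self.group!r}"
            )
        if self.parity not in PARITIES:
            raise ParseError(
                f"participant {self.participant_id}: unknown parity {self.parity!r}"
            )
        for vid, evs in self.events.items():
            evs.sort(key=lambda e: e.onset_s)
            validate_event_list(evs, f"participant {self.participant_id}, video {vid}")

    def all_events(self) -> List[BlinkEvent]:
        out: List[BlinkEvent] = []
        for vid in sorted(self.events):
            out.extend(self.events[vid])
        return out

    def n_blinks(self) -> int:
        return sum(len(v) for v in self.events.values())


def validate_record_against_schedules(
    record: ParticipantRecord, schedules: Dict[str, SceneSchedule]
) -> None:
    """Cross-checks that require the schedule table.

    Every video with events must have a schedule, and the parity label must be
    consistent with group x first-scene-category for every video watched.
    """
    for vid in record.events:
        if vid not in schedules:
            raise ValidationError(
                f"participant {record.participant_id}: video {vid!r} has no schedule"
            )
        want = expected_parity(record.group, schedules[vid].first_category)
        if want != record.parity:
            raise ValidationError(
                f"participant {record.participant_id}: parity {record.parity!r} "
                f"inconsistent with group {record.group!r} and first scene of "
                f"video {vid!r} (expected {want!r})"
            )


@dataclass
class PupilTrace:
    """Uniformly sampled pupil diameter and vertical pupil-center position.

    ``diameter`` is in arbitrary device units, ``center_y`` in pixels,
    ``valid`` flags samples where the tracker found a pupil.
    """

    sample_rate_hz: float
    t: np.ndarray
    diameter: np.ndarray
    center_y: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.diameter = np.asarray(self.diameter, dtype=float)
        self.center_y = np.asarray(self.center_y, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = len(self.t)
        if not (len(self.diameter) == len(self.center_y) == len(self.valid) == n):
            raise ValidationError("trace channels must have equal length")
        if n >= 2:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise ValidationError("trace times must be strictly increasing")
            expected = 1.0 / self.sample_rate_hz
            if np.max(np.abs(dt - expected)) > 1e-6:
                raise ValidationError(
                    "trace spacing must be uniform at 1/sample_rate_hz"
                )

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration_s(self) -> float:
        return len(self) / self.sample_rate_hz


@dataclass
class RateProfile:
    """Concatenated per-interval blink rates for one participant.

    ``values`` are blinks/minute over consecutive fixed-length intervals,
    concatenated across videos in a fixed order (sorted by condition).
    """

    participant_id: str
    interval_s: float
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValidationError(
                f"rate profile for {self.participant_id}: negative rate"
            )

    def __len__(self) -> int:
        return len(self.values)


def expected_profile_length(
    video_durations_s: Sequence[float], interval_s: float
) -> int:
    return int(sum(math.floor(d / interval_s + 1e-9) for d in video_durations_s))
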