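"""Readers and writers for the pipeline's CSV interchange formats.

All files are comma-separated UTF-8 with a mandatory header row and '.'
decimal point.  Floats are written with ``repr`` so that write-then-read is
the identity (bit-exact for integers, exact round-trip for binary floats).
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Union

import numpy as np

from .types import (
    BlinkEvent,
    ParseError,
    ParticipantRecord,
    PupilTrace,
    Scene,
    SceneSchedule,
    ValidationError,
    validate_event_list,
)

PathLike = Union[str, Path]

SCHEDULE_HEADER = ["video_id", "condition_s", "scene_index", "category", "onset_s", "offset_s"]
EVENTS_HEADER = ["participant_id", "group", "parity", "video_id", "onset_s", "duration_s"]
PARTICIPANTS_HEADER = ["participant_id", "group", "parity"]
TRACE_HEADER = ["t", "diameter", "center_y", "valid"]


def _fmt(x: float) -> str:
    """Shortest exact decimal representation of a float."""
    if float(x) == int(x):
        return str(int(x))
    return repr(float(x))


def _open_reader(path: PathLike, expected_header: List[str]) -> Iterable[Dict[str, str]]:
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file, expected header {expected_header}")
        if [h.strip() for h in header] != expected_header:
            raise ParseError(
                f"{path}: bad header {header!r}, expected {expected_header}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != len(expected_header):
                raise ParseError(
                    f"{path}, line {lineno}: expected {len(expected_header)} "
                    f"fields, got {len(row)}"
                )
            yield dict(zip(expected_header, row), _lineno=str(lineno))


def _parse_float(value: str, path: PathLike, lineno: str, field: str) -> float:
    try:
        return float(value)
    except ValueError:
        raise ParseError(f"{path}, line {lineno}: bad {field} value {value!r}")


# ---------------------------------------------------------------------------
# Scene schedules


def read_schedule(path: PathLike, enforce_envelope: bool = True) -> List[SceneSchedule]:
    """Read scene schedules; rows must be grouped per video, scenes in order."""
    rows_by_video: Dict[str, List[dict]] = {}
    order: List[str] = []
    for row in _open_reader(path, SCHEDULE_HEADER):
        vid = row["video_id"]
        if vid not in rows_by_video:
            rows_by_video[vid] = []
            order.append(vid)
        rows_by_video[vid].append(row)

    schedules = []
    for vid in order:
        rows = sorted(
            rows_by_video[vid], key=lambda r: int(_parse_float(r["scene_index"], path, r["_lineno"], "scene_index"))
        )
        conditions = {r["condition_s"] for r in rows}
        if len(conditions) != 1:
            raise ValidationError(f"schedule {vid}: inconsistent condition_s values")
        scenes = [
            Scene(
                index=int(_parse_float(r["scene_index"], path, r["_lineno"], "scene_index")),
                category=r["category"],
                onset_s=_parse_float(r["onset_s"], path, r["_lineno"], "onset_s"),
                offset_s=_parse_float(r["offset_s"], path, r["_lineno"], "offset_s"),
            )
            for r in rows
        ]
        sched = SceneSchedule(
            video_id=vid,
            condition_s=_parse_float(rows[0]["condition_s"], path, rows[0]["_lineno"], "condition_s"),
            scenes=scenes,
        )
        if enforce_envelope:
            sched.validate_duration_envelope()
        schedules.append(sched)
    return schedules


def write_schedule(schedules: Sequence[SceneSchedule], path: PathLike) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(SCHEDULE_HEADER)
        for sched in schedules:
            for sc in sched.scenes:
                writer.writerow(
                    [
                        sched.video_id,
                        _fmt(sched.condition_s),
                        sc.index,
                        sc.category,
                        _fmt(sc.onset_s),
                        _fmt(sc.offset_s),
                    ]
                )


# ---------------------------------------------------------------------------
# Blink events and participant metadata


def read_participants(path: PathLike) -> List[ParticipantRecord]:
    """Read participant metadata (no events attached yet)."""
    records = []
    seen = set()
    for row in _open_reader(path, PARTICIPANTS_HEADER):
        pid = row["participant_id"]
        if pid in seen:
            raise ParseError(f"{path}, line {row['_lineno']}: duplicate participant {pid!r}")
        seen.add(pid)
        records.append(
            ParticipantRecord(participant_id=pid, group=row["group"], parity=row["parity"])
        )
    return records


def write_participants(records: Sequence[ParticipantRecord], path: PathLike) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(PARTICIPANTS_HEADER)
        for rec in records:
            writer.writerow([rec.participant_id, rec.group, rec.parity])


def read_events(
    path: PathLike, participants_path: Optional[PathLike] = None
) -> List[ParticipantRecord]:
    """Read blink events grouped per participant and video.

    If ``participants_path`` is given, participants present in the metadata
    file but with zero blink rows are returned with empty event maps, and
    group/parity labels are cross-checked between the two files.
    """
    base: Dict[str, ParticipantRecord] = {}
    order: List[str] = []
    if participants_path is not None:
        for rec in read_participants(participants_path):
            base[rec.participant_id] = rec
            order.append(rec.participant_id)

    for row in _open_reader(path, EVENTS_HEADER):
        pid = row["participant_id"]
        if pid not in base:
            if participants_path is not None:
                raise ParseError(
                    f"{path}, line {row['_lineno']}: participant {pid!r} "
                    "not in participants file"
                )
            base[pid] = ParticipantRecord(
                participant_id=pid, group=row["group"], parity=row["parity"]
            )
            order.append(pid)
        rec = base[pid]
        if rec.group != row["group"] or rec.parity != row["parity"]:
            raise ParseError(
                f"{path}, line {row['_lineno']}: labels for {pid!r} disagree "
                "with earlier rows or participants file"
            )
        event = BlinkEvent(
            onset_s=_parse_float(row["onset_s"], path, row["_lineno"], "onset_s"),
            duration_s=_parse_float(row["duration_s"], path, row["_lineno"], "duration_s"),
        )
        rec.events.setdefault(row["video_id"], []).append(event)

    records = [base[pid] for pid in order]
    for rec in records:
        for vid, evs in rec.events.items():
            evs.sort(key=lambda e: e.onset_s)
            validate_event_list(evs, f"participant {rec.participant_id}, video {vid}")
    return records


def write_events(records: Sequence[ParticipantRecord], path: PathLike) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(EVENTS_HEADER)
        for rec in records:
            for vid in sorted(rec.events):
                for ev in rec.events[vid]:
                    writer.writerow(
                        [
                            rec.participant_id,
                            rec.group,
                            rec.parity,
                            vid,
                            _fmt(ev.onset_s),
                            _fmt(ev.duration_s),
                        ]
                    )


# ---------------------------------------------------------------------------
# Pupil traces


def read_trace(path: PathLike, sample_rate_hz: float) -> PupilTrace:
    t, diameter, center_y, valid = [], [], [], []
    for row in _open_reader(path, TRACE_HEADER):
        t.append(_parse_float(row["t"], path, row["_lineno"], "t"))
        diameter.append(_parse_float(row["diameter"], path, row["_lineno"], "diameter"))
        center_y.append(_parse_float(row["center_y"], path, row["_lineno"], "center_y"))
        v = row["valid"].strip()
        if v not in ("0", "1"):
            raise ParseError(f"{path}, line {row['_lineno']}: valid must be 0 or 1")
        valid.append(v == "1")
    return PupilTrace(
        sample_rate_hz=sample_rate_hz,
        t=np.array(t),
        diameter=np.array(diameter),
        center_y=np.array(center_y),
        valid=np.array(valid),
    )


def write_trace(trace: PupilTrace, path: PathLike) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(TRACE_HEADER)
        for i in range(len(trace)):
            writer.writerow(
                [
                    _fmt(trace.t[i]),
                    _fmt(trace.diameter[i]),
                    _fmt(trace.center_y[i]),
                    1 if trace.valid[i] else 0,
                ]
            )
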