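"""Blink detection from pupil occlusion dynamics.

A blink occludes the pupil: the measured diameter collapses rapidly to zero
while the apparent pupil center is dragged downward by the closing lid, and
the tracker loses the pupil (``valid`` flips false) at full occlusion.  The
detector keys on those two signals — rate of change of pupil diameter, and
vertical displacement of the pupil center co-occurring with track dropout —
then reconstructs each blink's onset and duration by sub-sample interpolation
of the occlusion ramps.

Invalid runs *without* the rapid-occlusion signature (e.g. off-screen
fixations or head movement) never open a candidate and are reported as track
loss, not blinks.

Analysis runs at 30 Hz; traces recorded at 60 Hz are down-sampled first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .types import BlinkEvent, PupilTrace, ValidationError
from .synth import RAMP_FRACTION

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DetectorParams:
    """Detection thresholds.

    diameter_drop_rate
        Minimum per-sample diameter decrease, as a fraction of the local
        baseline diameter, to open a blink candidate.
    center_y_disp
        Minimum vertical pupil-center displacement, in units of the baseline
        center-position SD, required for a track dropout to co-signal a blink.
    min_dur_s, max_dur_s
        Plausible blink duration window; candidates outside it are discarded.
    merge_gap_s
        Candidates separated by less than this are merged (flutter re-opens).
    close_fraction
        Diameter recovery level (fraction of local baseline) that closes a
        candidate; also the level used for sub-sample ramp interpolation.
    ramp_fraction
        Assumed fraction of a blink spent on each lid ramp, used to convert
        the interpolated half-recovery width into a full blink duration.
    """

    diameter_drop_rate: float = 0.30
    center_y_disp: float = 2.0
    min_dur_s: float = 0.05
    max_dur_s: float = 1.0
    merge_gap_s: float = 0.05
    close_fraction: float = 0.5
    ramp_fraction: float = RAMP_FRACTION

    def __post_init__(self) -> None:
        if not 0 < self.min_dur_s < self.max_dur_s:
            raise ValidationError("need 0 < min_dur_s < max_dur_s")
        if self.merge_gap_s < 0:
            raise ValidationError("merge_gap_s must be >= 0")
        if not 0 < self.close_fraction < 1:
            raise ValidationError("close_fraction must be in (0, 1)")


@dataclass(frozen=True)
class DetectionQuality:
    track_loss: bool
    valid_fraction: float
    n_samples: int


def downsample(trace: PupilTrace) -> PupilTrace:
    """60 Hz -> 30 Hz by averaging consecutive sample pairs.

    ``valid`` is the logical AND of each pair; an odd trailing sample is
    dropped with a warning.
    """
    if abs(trace.sample_rate_hz - 60.0) > 1e-9:
        raise ValidationError(
            f"downsample expects a 60 Hz trace, got {trace.sample_rate_hz} Hz"
        )
    n = len(trace)
    if n % 2:
        logger.warning("odd sample count %d; dropping final unpaired sample", n)
        n -= 1
    pairs = slice(0, n)
    t = trace.t[pairs].reshape(-1, 2).mean(axis=1)
    diameter = trace.diameter[pairs].reshape(-1, 2).mean(axis=1)
    center_y = trace.center_y[pairs].reshape(-1, 2).mean(axis=1)
    valid = trace.valid[pairs].reshape(-1, 2).all(axis=1)
    return PupilTrace(
        sample_rate_hz=30.0, t=t, diameter=diameter, center_y=center_y, valid=valid
    )


def _find_candidates(
    trace: PupilTrace, params: DetectorParams
) -> List[Tuple[int, int]]:
    """Raw candidate (open_index, close_index) pairs, before merge/filter."""
    diam = trace.diameter
    valid = trace.valid
    n = len(diam)
    baseline = float(np.median(diam[valid]))
    if baseline <= 0:
        return []
    cy = trace.center_y
    cy_base = float(np.median(cy[valid]))
    cy_sd = float(np.std(cy[valid]))
    cy_thresh = params.center_y_disp * cy_sd  # 0 when noiseless: any deflection

    close_level = params.close_fraction * baseline
    candidates = []
    i = 1
    while i < n:
        drop = (diam[i - 1] - diam[i]) / baseline
        dropout = valid[i - 1] and not valid[i] and abs(cy[i] - cy_base) >= cy_thresh
        if drop >= params.diameter_drop_rate or dropout:
            j = i + 1
            while j < n and not (diam[j] >= close_level and valid[j]):
                j += 1
            close = min(j, n - 1)
            candidates.append((i, close))
            i = close + 1
        else:
            i += 1
    return candidates


def _refine(
    trace: PupilTrace, open_i: int, close_i: int, params: DetectorParams
) -> Optional[BlinkEvent]:
    """Sub-sample onset/duration estimate from the occlusion ramp crossings.

    Interpolates the times at which the diameter crosses the
    ``close_fraction`` level on the way down and back up; under a trapezoidal
    lid model with ramp fraction r and crossing level 1/2, the half-level
    width equals ``duration * (1 - r)`` and the onset precedes the first
    crossing by ``r * duration / 2``.
    """
    diam = trace.diameter
    t = trace.t
    n = len(diam)
    lo = max(open_i - 2, 0)
    hi = min(close_i + 1, n - 1)
    pre = diam[max(open_i - 16, 0) : open_i]
    pre_valid = trace.valid[max(open_i - 16, 0) : open_i]
    local_baseline = (
        float(np.median(pre[pre_valid]))
        if pre_valid.any()
        else float(np.median(diam[trace.valid]))
    )
    level = params.close_fraction * local_baseline

    below = None
    for k in range(lo + 1, hi + 1):
        if diam[k] < level <= diam[k - 1]:
            below = k
            break
    if below is None:
        return None
    denom = diam[below - 1] - diam[below]
    t_on_half = t[below - 1] + (diam[below - 1] - level) / denom * (
        t[below] - t[below - 1]
    )

    above = None
    for k in range(hi, below - 1, -1):
        if diam[k] < level and k + 1 <= hi and diam[k + 1] >= level:
            above = k
            break
    if above is None:
        # never recovered within the candidate; fall back to the close sample
        above = hi - 1 if hi - 1 >= below else below
        if diam[min(above + 1, n - 1)] < level:
            return None
    denom = diam[above + 1] - diam[above]
    t_off_half = t[above] + (level - diam[above]) / denom * (t[above + 1] - t[above])

    width = t_off_half - t_on_half
    if width <= 0:
        return None
    r = params.ramp_fraction
    duration = width / (1.0 - r)
    onset = t_on_half - r * duration / 2.0
    return BlinkEvent(onset_s=float(onset), duration_s=float(duration))


def detect_blinks_full(
    trace: PupilTrace, params: Optional[DetectorParams] = None
) -> Tuple[List[BlinkEvent], DetectionQuality]:
    """Detect blinks and report trace quality.

    An all-invalid trace yields no events and a track-loss flag — that is
    lost tracking, not blinking.
    """
    params = params or DetectorParams()
    n = len(trace)
    valid_frac = float(np.mean(trace.valid)) if n else 0.0
    if n == 0 or not trace.valid.any():
        return [], DetectionQuality(track_loss=True, valid_fraction=valid_frac, n_samples=n)

    candidates = _find_candidates(trace, params)

    # merge candidates separated by less than merge_gap_s
    dt = 1.0 / trace.sample_rate_hz
    merged: List[Tuple[int, int]] = []
    for cand in candidates:
        if merged and (cand[0] - merged[-1][1]) * dt <= params.merge_gap_s:
            merged[-1] = (merged[-1][0], cand[1])
        else:
            merged.append(cand)

    events = []
    for open_i, close_i in merged:
        ev = _refine(trace, open_i, close_i, params)
        if ev is None:
            continue
        if params.min_dur_s <= ev.duration_s <= params.max_dur_s:
            events.append(ev)

    # enforce sorted, non-overlapping output
    events.sort(key=lambda e: e.onset_s)
    cleaned: List[BlinkEvent] = []
    for ev in events:
        if cleaned and ev.onset_s < cleaned[-1].offset_s:
            continue
        cleaned.append(ev)
    quality = DetectionQuality(
        track_loss=False, valid_fraction=valid_frac, n_samples=n
    )
    return cleaned, quality


def detect_blinks(
    trace: PupilTrace, params: Optional[DetectorParams] = None
) -> List[BlinkEvent]:
    events, quality = detect_blinks_full(trace, params)
    if quality.track_loss:
        logger.warning("trace has no valid samples: track loss, not blinks")
    return events


@dataclass(frozen=True)
class DetectionReport:
    n_truth: int
    n_detected: int
    n_matched: int
    sensitivity_pct: float
    false_alarms_per_min: float
    mean_abs_onset_error_s: float
    mean_abs_duration_error_s: float


def detection_report(
    truth: Sequence[BlinkEvent],
    detected: Sequence[BlinkEvent],
    match_tol_s: float,
    duration_s: Optional[float] = None,
) -> DetectionReport:
    """Score detections against ground truth by greedy one-to-one onset matching."""
    if match_tol_s <= 0:
        raise ValidationError("match_tol_s must be > 0")
    truth = sorted(truth, key=lambda e: e.onset_s)
    detected = sorted(detected, key=lambda e: e.onset_s)
    used = np.zeros(len(detected), dtype=bool)
    onset_errs, dur_errs = [], []
    for ev in truth:
        best, best_err = None, match_tol_s
        for j, d in enumerate(detected):
            if used[j]:
                continue
            err = abs(d.onset_s - ev.onset_s)
            if err <= best_err:
                best, best_err = j, err
            if d.onset_s - ev.onset_s > match_tol_s:
                break
        if best is not None:
            used[best] = True
            onset_errs.append(best_err)
            dur_errs.append(abs(detected[best].duration_s - ev.duration_s))
    n_matched = len(onset_errs)
    if duration_s is None:
        ends = [e.offset_s for e in list(truth) + list(detected)]
        duration_s = max(ends) if ends else 0.0
    fa = len(detected) - n_matched
    return DetectionReport(
        n_truth=len(truth),
        n_detected=len(detected),
        n_matched=n_matched,
        sensitivity_pct=100.0 * n_matched / len(truth) if truth else 100.0,
        false_alarms_per_min=60.0 * fa / duration_s if duration_s > 0 else 0.0,
        mean_abs_onset_error_s=float(np.mean(onset_errs)) if onset_errs else 0.0,
        mean_abs_duration_error_s=float(np.mean(dur_errs)) if dur_errs else 0.0,
    )
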