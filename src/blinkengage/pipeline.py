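"""End-to-end orchestration: simulate -> (detect) -> rates -> classifiers ->
strength -> stats, with one config, derived per-stage seeds, and a JSON run
manifest.

Per-stage seeds are derived from the global seed by hashing the stage name,
so reconfiguring one stage never perturbs another stage's randomness.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import io as bio
from .content_aware import classify_content_aware
from .content_unaware import SVMConfig, build_features, loocv_classify, permutation_test
from .detect import DetectorParams, detect_blinks_full, downsample
from .rates import instantaneous_rate, interval_vector, scene_rates
from .stats import (
    interaction_anova,
    normality_check,
    timescale_paired_tests,
    two_sample_t,
)
from .strength import cohort_likelihoods, deming_fit, strength_regressions
from .synth import (
    CohortParams,
    DEFAULT_TARGET_DURATION_S,
    make_schedule_sets,
    render_pupil_trace,
    simulate_cohort,
)
from .types import (
    CONDITIONS_S,
    GROUP_LAND,
    GROUP_WATER,
    ParticipantRecord,
    SceneSchedule,
    ValidationError,
    validate_record_against_schedules,
)

logger = logging.getLogger(__name__)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    return (int(global_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class RunConfig:
    cohort: CohortParams = field(default_factory=CohortParams)
    detector: DetectorParams = field(default_factory=DetectorParams)
    svm: SVMConfig = field(default_factory=SVMConfig)
    intervals_s: Tuple[float, ...] = tuple(float(k) for k in range(1, 11))
    conditions_s: Tuple[float, ...] = tuple(float(c) for c in CONDITIONS_S)
    target_duration_s: float = DEFAULT_TARGET_DURATION_S
    n_perm: int = 1000
    exemplar_condition_s: float = 5.0
    render_traces: bool = False
    trace_noise_sd: float = 2.0  # device units; baseline diameter is 100
    output_dir: str = "blinkengage_run"
    global_seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "cohort" in kwargs:
            kwargs["cohort"] = CohortParams(**_tupled(kwargs["cohort"]))
        if "detector" in kwargs:
            kwargs["detector"] = DetectorParams(**kwargs["detector"])
        if "svm" in kwargs:
            kwargs["svm"] = SVMConfig(**_tupled(kwargs["svm"]))
        for key in ("intervals_s", "conditions_s"):
            if key in kwargs:
                kwargs[key] = tuple(float(v) for v in kwargs[key])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _tupled(d: dict) -> dict:
    return {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}


def run_full(config: RunConfig) -> dict:
    """Execute every stage and return (and write) the run manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "stage_seeds": {},
        "outputs": {},
        "headline": {},
        "timing_s": {},
    }

    def record(stage: str, started: float) -> None:
        manifest["timing_s"][stage] = round(time.perf_counter() - started, 3)
        logger.info("stage %s done in %.2f s", stage, manifest["timing_s"][stage])

    # --- simulate -----------------------------------------------------------
    t0 = time.perf_counter()
    sim_seed = stage_seed(config.global_seed, "simulate")
    manifest["stage_seeds"]["simulate"] = sim_seed
    cohort = replace(config.cohort, seed=sim_seed)
    records, schedules, profiles = simulate_cohort(
        cohort,
        target_duration_s=config.target_duration_s,
        conditions=config.conditions_s,
    )
    for rec in records:
        validate_record_against_schedules(rec, schedules)
    bio.write_schedule(
        sorted(schedules.values(), key=lambda s: s.video_id), out / "schedules.csv"
    )
    bio.write_participants(records, out / "participants.csv")
    bio.write_events(records, out / "events.csv")
    manifest["outputs"]["schedules"] = "schedules.csv"
    manifest["outputs"]["events"] = "events.csv"
    record("simulate", t0)

    # --- optional detector round-trip --------------------------------------
    if config.render_traces:
        t0 = time.perf_counter()
        det_seed = stage_seed(config.global_seed, "detect")
        manifest["stage_seeds"]["detect"] = det_seed
        rng = np.random.default_rng(det_seed)
        quality = {}
        for rec in records:
            for vid, events in rec.events.items():
                sched = schedules[vid]
                trace = render_pupil_trace(
                    events,
                    duration_s=sched.duration_s,
                    sample_rate_hz=60.0,
                    noise_sd=config.trace_noise_sd,
                    seed_or_rng=rng,
                )
                detected, q = detect_blinks_full(downsample(trace), config.detector)
                rec.events[vid] = detected
                quality[f"{rec.participant_id}/{vid}"] = dataclasses.asdict(q)
        (out / "detection_quality.json").write_text(json.dumps(quality, indent=1))
        bio.write_events(records, out / "events_detected.csv")
        manifest["outputs"]["events_detected"] = "events_detected.csv"
        record("detect", t0)

    # --- rates --------------------------------------------------------------
    t0 = time.perf_counter()
    all_rates = {rec.participant_id: scene_rates(rec, schedules) for rec in records}
    rows = []
    for rec in records:
        r = all_rates[rec.participant_id]
        rows.append(
            dict(
                participant_id=rec.participant_id,
                group=rec.group,
                parity=rec.parity,
                bpm_session=r.bpm_session,
                bpm_land=r.bpm_land,
                bpm_water=r.bpm_water,
                bpm_relevant=r.bpm_relevant,
                bpm_irrelevant=r.bpm_irrelevant,
                metric=r.metric,
            )
        )
    pd.DataFrame(rows).to_csv(out / "scene_rates.csv", index=False)

    profile_rows = []
    for rec in records:
        for interval in config.intervals_s:
            prof = interval_vector(rec, schedules, interval)
            for k, v in enumerate(prof.values):
                profile_rows.append(
                    dict(
                        participant_id=rec.participant_id,
                        interval_s=interval,
                        bin_index=k,
                        bpm=v,
                    )
                )
    pd.DataFrame(profile_rows).to_csv(out / "rate_profiles.csv", index=False)

    # exemplar smoothed group rate (one condition, both groups)
    cond = config.exemplar_condition_s
    inst_rows = []
    for group in (GROUP_LAND, GROUP_WATER):
        sets = []
        duration = None
        for rec in records:
            if rec.group != group:
                continue
            for vid, events in rec.events.items():
                if schedules[vid].condition_s == cond:
                    sets.append(events)
                    duration = schedules[vid].duration_s
        if sets and duration:
            t, rate = instantaneous_rate(sets, duration)
            inst_rows.append(
                pd.DataFrame({"t_s": t, "group": group, "rate_bpm": rate})
            )
    if inst_rows:
        pd.concat(inst_rows).to_csv(out / "instantaneous_rate.csv", index=False)
    manifest["outputs"]["scene_rates"] = "scene_rates.csv"
    record("rates", t0)

    # --- content-aware classifier -------------------------------------------
    t0 = time.perf_counter()
    metrics = [all_rates[rec.participant_id].metric for rec in records]
    groups = [rec.group for rec in records]
    roc = classify_content_aware(metrics, groups)
    pd.DataFrame(
        {"threshold": roc.thresholds, "tpr": roc.tpr, "fpr": roc.fpr}
    ).to_csv(out / "roc.csv", index=False)
    manifest["headline"]["auc"] = roc.auc
    manifest["headline"]["sensitivity_pct"] = roc.sensitivity_at_optimal
    manifest["headline"]["specificity_pct"] = roc.specificity_at_optimal
    manifest["headline"]["ci_sensitivity_pct"] = list(roc.ci_sensitivity)
    manifest["headline"]["ci_specificity_pct"] = list(roc.ci_specificity)
    record("content_aware", t0)

    # --- content-unaware classifier -----------------------------------------
    t0 = time.perf_counter()
    svm_seed = stage_seed(config.global_seed, "classify_unaware")
    manifest["stage_seeds"]["classify_unaware"] = svm_seed
    svm_config = replace(config.svm, seed=svm_seed)
    table_rows = []
    for interval in config.intervals_s:
        features = build_features(records, schedules, interval)
        if config.n_perm > 0:
            report = permutation_test(features, svm_config, n_perm=config.n_perm)
            np.savetxt(
                out / f"null_distribution_{int(interval):02d}s.csv",
                report.null_accuracies,
                header="null_accuracy_pct",
                comments="",
                fmt="%.6f",
            )
        else:
            report = loocv_classify(features, svm_config)
        table_rows.append(
            dict(
                interval_s=interval,
                n_correct=report.n_correct,
                percent_correct=report.percent_correct,
                p_value=report.p_value,
                cutoff_95=report.cutoff_95,
            )
        )
    table = pd.DataFrame(table_rows)
    table.to_csv(out / "content_unaware.csv", index=False)
    manifest["headline"]["percent_correct_by_interval"] = {
        str(r["interval_s"]): r["percent_correct"] for r in table_rows
    }
    manifest["headline"]["min_n_correct"] = int(table["n_correct"].min())
    if config.n_perm > 0:
        manifest["headline"]["permutation_p_by_interval"] = {
            str(r["interval_s"]): r["p_value"] for r in table_rows
        }
    record("content_unaware", t0)

    # --- classification strength --------------------------------------------
    t0 = time.perf_counter()
    lik_rows, reg_rows = [], []
    for cond in config.conditions_s:
        pids = [rec.participant_id for rec in records]
        cond_metrics = [all_rates[p].by_condition[cond].metric for p in pids]
        results = cohort_likelihoods(pids, cond_metrics, groups, condition_s=cond)
        x_bpm = [all_rates[p].by_condition[cond].bpm_session for p in pids]
        y_loglr = [r.log_lr for r in results]
        for r in results:
            lik_rows.append(dataclasses.asdict(r))
        try:
            fits = strength_regressions(
                x_bpm, y_loglr, condition_s=cond, n_comparisons=len(config.conditions_s)
            )
            for f in fits:
                row = dataclasses.asdict(f)
                row["coefficients"] = json.dumps(list(f.coefficients))
                reg_rows.append(row)
            slope, intercept = deming_fit(x_bpm, y_loglr)
            reg_rows.append(
                dict(
                    condition_s=cond,
                    form="deming",
                    coefficients=json.dumps([intercept, slope]),
                    r_squared=float("nan"),
                    p_value=float("nan"),
                    p_bonferroni=float("nan"),
                    converged=True,
                )
            )
        except ValidationError as exc:
            logger.warning("condition %s: strength regression skipped (%s)", cond, exc)
    pd.DataFrame(lik_rows).to_csv(out / "likelihood.csv", index=False)
    pd.DataFrame(reg_rows).to_csv(out / "regressions.csv", index=False)
    record("strength", t0)

    # --- group statistics ---------------------------------------------------
    t0 = time.perf_counter()
    stat_rows = []
    session = np.array([all_rates[r.participant_id].bpm_session for r in records])
    garr = np.array(groups)
    res_t = two_sample_t(
        session[garr == GROUP_LAND], session[garr == GROUP_WATER],
        name="overall_bpm_two_sample_t",
    )
    stat_rows.append(res_t)
    for group in (GROUP_LAND, GROUP_WATER):
        stat_rows.append(
            normality_check(session[garr == group], name=f"shapiro_{group}")
        )
    land = [all_rates[r.participant_id].bpm_land for r in records]
    water = [all_rates[r.participant_id].bpm_water for r in records]
    res_int = interaction_anova(land, water, groups)
    stat_rows.append(res_int)
    rel_by_cond = {
        c: [all_rates[r.participant_id].by_condition[c].bpm_relevant for r in records]
        for c in config.conditions_s
    }
    irr_by_cond = {
        c: [all_rates[r.participant_id].by_condition[c].bpm_irrelevant for r in records]
        for c in config.conditions_s
    }
    ts_results = timescale_paired_tests(rel_by_cond, irr_by_cond)
    stat_rows.extend(ts_results)
    pd.DataFrame([dataclasses.asdict(r) for r in stat_rows]).to_csv(
        out / "stats.csv", index=False
    )
    manifest["headline"]["interaction_F"] = res_int.statistic
    manifest["headline"]["interaction_p"] = res_int.p_value
    corrected = [r.p_corrected for r in ts_results if r.p_corrected is not None]
    manifest["headline"]["timescale_all_significant"] = bool(
        corrected and max(corrected) < 0.05
    )
    record("stats", t0)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
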