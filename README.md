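# blinkengage

Blink-rate measures of viewer engagement.

People blink less while watching content they perceive as important: blink
inhibition minimizes the loss of visual information at exactly the moments a
viewer cares about most.  `blinkengage` turns that phenomenon into a tested
analysis pipeline for a two-task viewing design in which participants watch
composite videos alternating between two scene categories (land and water
animal scenes, at a constant per-video rate of 1, 5, 10, ..., 60 s) while
counting animals of one category.  Scenes relevant to the assigned counting
task are, by design, more engaging — and blink rates drop during them.

The package is aimed at researchers who want to analyze (or prototype
analyses of) pupillometry-based blink data: it ships a synthetic-data
generator that emulates the study's blink statistics, so every stage can be
developed and validated without access to raw eye-tracking recordings.

## What it computes

- **Blink detection** (`blinkengage.detect`): blinks in a pupil trace are
  found from occlusion dynamics — a rapid drop in measured pupil diameter
  together with a downward displacement of the pupil center and tracker
  dropout — with sub-sample onset/duration estimates; 60 Hz traces are
  down-sampled to the 30 Hz analysis rate.  Invalid runs without the
  occlusion signature are reported as track loss, not blinks.
- **Rate metrics** (`blinkengage.rates`): blinks per minute (BPM) pooled
  over arbitrary window sets, per scene category, per timing condition, as
  interval-averaged feature vectors, and as a Gaussian-smoothed instantaneous
  group rate.
- **Content-aware classification** (`blinkengage.content_aware`): each
  participant's `bpm_land − bpm_water` metric classifies their task group.
  Full empirical ROC sweep, trapezoidal AUC, Youden-optimal threshold, and
  exact Clopper–Pearson confidence intervals for sensitivity/specificity.
- **Content-unaware classification** (`blinkengage.content_unaware`): a
  linear SVM on interval-averaged BPM vectors (no knowledge of scene timing)
  predicts which counterbalancing parity a participant attended, with
  leave-one-out cross-validation, per-fold regularization selection
  (C = 10⁻²…10¹⁰, inner 75/25 split), and a label-permutation null.
- **Classification strength** (`blinkengage.strength`): per-condition kernel
  density estimates of each group's metric give a likelihood ratio
  `LR = p(metric | correct group) / p(metric | incorrect group)`; a
  regression suite (linear/quadratic/cubic/exponential, Bonferroni-corrected
  over the 13 conditions) plus a Deming errors-in-variables fit relate
  log(LR) to individual blink rate.
- **Group statistics** (`blinkengage.stats`): Shapiro–Wilk checks, pooled
  two-sample t, the scene×group mixed-design interaction (computed via the
  exact F = t² identity for a two-level within factor), and per-timescale
  paired t-tests with Bonferroni–Holm correction.
- **Synthetic data** (`blinkengage.synth`): cohorts with truncated-normal
  baseline rates calibrated so the *observed* rates have mean 12.6 bpm,
  SD 6.7 bpm and range 2–26 bpm; blink streams from a dead-time-compensated
  piecewise Poisson process with task-locked suppression (intensity λρ in
  task-relevant scenes, λ(2−ρ) in irrelevant ones, preserving the session
  mean λ); and pupil-trace rendering as the inverse of the detector.

## Worked example

```python
from blinkengage import (
    CohortParams, SVMConfig, simulate_cohort, build_features,
    loocv_classify, classify_content_aware, scene_rates,
)

records, schedules, profiles = simulate_cohort(CohortParams(seed=42))
rates = [scene_rates(r, schedules) for r in records]
roc = classify_content_aware([r.metric for r in rates], [r.group for r in rates])
print(f"AUC: {roc.auc:.3f}  sensitivity: {roc.sensitivity_at_optimal:.1f}%  "
      f"specificity: {roc.specificity_at_optimal:.1f}%")
print(f"95% CIs: sensitivity {roc.ci_sensitivity[0]:.1f}-{roc.ci_sensitivity[1]:.1f}%, "
      f"specificity {roc.ci_specificity[0]:.1f}-{roc.ci_specificity[1]:.1f}%")
for interval in (1.0, 5.0, 10.0):
    feats = build_features(records, schedules, interval)
    report = loocv_classify(feats, SVMConfig(seed=1))
    print(f"interval {interval:4.0f} s: {report.n_correct}/21 correct "
          f"({report.percent_correct:.2f}%)")
```

prints

```
AUC: 1.000  sensitivity: 100.0%  specificity: 100.0%
95% CIs: sensitivity 71.5-100.0%, specificity 69.2-100.0%
interval    1 s: 21/21 correct (100.00%)
interval    5 s: 21/21 correct (100.00%)
interval   10 s: 21/21 correct (100.00%)
```

The default cohort simulates 11 land counters and 10 water counters with a
suppression ratio of 0.5, so every participant blinks less during scenes
relevant to their task.  The content-aware metric then separates the two
groups completely (AUC = 1, sensitivity and specificity 100%), and the
content-unaware SVM recovers the attended parity for 21 of 21 participants
here; the confidence intervals reflect the small group sizes (exact binomial
lower bounds of 71.5% and 69.2% at 11/11 and 10/10 successes).

A full run — simulation, rates, both classifiers, likelihood ratios,
regression suite and statistics, with all CSV outputs and a JSON manifest —
is one call (or `blinkengage run-full` from a shell):

```python
from blinkengage import RunConfig, run_full
manifest = run_full(RunConfig(output_dir="out", global_seed=7, n_perm=1000))
```

The CLI mirrors the stages: `blinkengage simulate | detect | rates |
classify-aware | classify-unaware | strength | stats | run-full`.

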