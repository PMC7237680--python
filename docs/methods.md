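# Methods

This note documents the models and procedures implemented in `blinkengage`,
the assumptions behind them, the defaults that matter, and what the synthetic
study does and does not emulate.

## The study design being modeled

Twenty-one adults (11 "land counters", 10 "water counters") watch 13
composite videos, each alternating between land-animal and water-animal
scenes at a constant per-video rate drawn from {1, 5, 10, ..., 60} s.  All
scenes within a video have the same duration, categories strictly alternate,
and videos run 1.5–2.67 minutes.  Each group counts animals of one category,
making that category's scenes task-relevant and hence more engaging.  Half of
each group sees videos starting with a land scene and half with a water
scene; a participant whose task-relevant scenes occupy odd positions is
labeled `attended_odd`, otherwise `attended_even`.  Analysis time is seconds
from the onset of the alternating scene content; instruction and response
screens are excluded (whether they contributed to published session-level
rates is not determinable from the available description — we exclude them
and flag the choice here).  Scene windows are half-open `[onset, offset)`:
a blink whose onset lands exactly on a boundary belongs to the later scene.

## Synthetic cohort generator

The generator is first-class, tested code: it defines the conditions under
which every downstream claim is checked.

**Baseline rates.**  Individual baseline blink rates are drawn from a
truncated normal on [2, 26] blinks/minute (bpm).  The published cohort
statistics (mean 12.6, SD 6.7, range 2–26 bpm) describe the *observed* rates,
which necessarily live inside the bounds — so the generator solves (by
2-D root finding on numerically integrated moments) for the parent normal
whose truncation has exactly mean 12.6 and SD 6.7.  The solution is
approximately N(−0.06, 21.4²): heavily truncated, close to uniform on the
range, which is what a truncated SD of 6.7 against the uniform-limit SD of
(26−2)/√12 ≈ 6.93 requires.  Naively truncating N(12.6, 6.7²) would instead
yield observed mean ≈ 13.04 and SD ≈ 5.8, contradicting two of the three
published statistics.  A degenerate `rate_sd_bpm = 0` bypasses calibration
and returns the mean.  Infeasible targets (mean outside bounds, SD at or
above the uniform limit) raise.

**Task-locked suppression.**  A participant with baseline rate λ and
suppression ratio ρ ∈ (0, 1] blinks with intensity λρ during task-relevant
scenes and λ(2−ρ) during irrelevant scenes.  This single-knob
parameterization encodes both the suppression and the complementary
elevation seen in the data while keeping the session mean at λ for every ρ
(relevant and irrelevant exposure are equal by construction, because scene
counts per video are even).  The default ρ = 0.5 is a calibration choice —
the within-participant effect size was not published — selected so that the
all-participants suppression effect holds with overwhelming probability at
the study's exposure (~30 min): at ρ = 0.5 the worst-case participant
(λ = 2 bpm) has a category-rate sign-reversal probability below 10⁻⁴ by
Poisson tails, so "every participant blinked less during relevant scenes" is
a forced outcome, as observed.  At ρ ≥ 0.7 that guarantee degrades (≈1%
reversal probability for the slowest blinkers), which is why the suite tests
the all-participants property at the default ρ only.

**Dead time and rate compensation.**  Blinks occupy time (durations uniform
on 150–400 ms, the typical physiological range) and cannot overlap, making
the stream a Poisson process with dead time.  Generating naively at the
target rate r would undershoot it, so the generator uses the compensated
intensity λ_gen = r/(1 − r·d̄), with d̄ = 275 ms the mean blink duration.
For a renewal process with exponential waits and random dead times this makes
the long-run realized rate equal r exactly (Wald's identity), giving the
tests closed-form oracles: simulated streams are checked against target
rates to within 3 standard errors over 10⁴ simulated minutes.  Residual
biases (start-of-video transients, dead time crossing scene boundaries) are
of order d̄ per video and scene boundary, well inside those bands at the
tested scale.

**Scene schedules.**  One video per condition: the scene count is the
largest even n with n·condition ≤ target duration (even, so both categories
get equal exposure; minimum 2).  The default 160 s target puts every one of
the 13 videos inside the study's 90–160.2 s envelope and yields ≈29.7 min of
scene time per participant.

**Pupil-trace rendering.**  The inverse of the detector, for round-trip
validation: baseline diameter 100 (arbitrary device units), trapezoidal lid
model (linear close over the first quarter of the blink, full occlusion,
linear reopen over the last quarter), pupil center deflected 40 px downward
at full occlusion, validity false while fully occluded, Gaussian measurement
noise added to valid samples.

**What the generator does not emulate.**  Blink synchrony between
participants, scene-transition-locked blink bursts, gaze position,
drowsiness/fatigue drifts, and any dependence of blink timing on scene
content beyond the two-level relevant/irrelevant intensity switch.  Passing
tests therefore demonstrate that the pipeline recovers the engagement
structure the generator encodes — not that real recordings would be as
clean.  In particular, real data degrade at the fastest alternation rates
(blink latencies smear 1 s scenes), while the generator's intensity switch
is instantaneous; synthetic classification results at short conditions are
accordingly optimistic, and the published real-data pattern (classification
strength relating to blink rate *only* at the 1 s condition) appears in the
synthetic data as a relationship at every condition.

## Blink detection

The published description names two occlusion signals (rate of change of
pupil diameter; vertical displacement of the pupil center) but no
thresholds, so all `DetectorParams` defaults are artifact choices validated
against the renderer: a candidate opens where the per-sample fractional
diameter drop is ≥ 0.30 of the local baseline **or** the validity flag drops
while the center is displaced ≥ 2 baseline SDs (OR logic, with the
displacement co-check gating dropouts — whether the original used AND or OR
is unstated; this is configurable).  A candidate closes when the diameter
recovers to ≥ 50% of the local pre-event baseline with valid tracking;
candidates closer than 50 ms merge; events outside [50 ms, 1 s] are
discarded.  Onset and duration are refined by linear interpolation of the
half-recovery crossings: under the trapezoidal lid model with ramp fraction
r, the half-level width equals duration·(1−r) and the onset precedes the
first crossing by r·duration/2.  This sub-sample estimate is what makes mean
duration errors below 10 ms achievable at a 33 ms sampling interval.
Detection runs at 30 Hz; 60 Hz traces are down-sampled by pair averaging
(validity AND; odd trailing sample dropped with a warning).  All-invalid
traces yield a track-loss flag and no events — invalid runs lacking the
rapid-occlusion signature are never counted as blinks.

The detector's published validation figures (95.0% / 96.4% agreement with
video and EMG coding) concern real recordings and are out of scope; the
synthetic benchmark (100 blinks, noise SD 5% of baseline diameter) mirrors
the validation scale instead: sensitivity ≥ 95%, mean duration error
< 10 ms.

## Rate metrics

Category BPM pools counts over exposure (total blinks / total seconds),
never averages per-scene rates — at 1 s scenes most per-scene counts are 0
and a mean-of-rates estimator would be dominated by discretization.  The
same pooling identity is tested explicitly on unequal windows.  Interval
feature vectors use consecutive fixed-length bins from video onset with the
trailing partial bin dropped (not rescaled), keeping feature dimensions
fixed across participants; videos concatenate in condition order.  The
smoothed instantaneous group rate convolves per-frame (30 Hz) mean onset
counts with a Gaussian kernel (default SD 1.0 s — the published smoothing
method is unspecified; a Gaussian is the standard rate-smoothing choice and
is conservation-testable), with truncated kernel mass renormalized at the
edges so the time integral of the rate conserves blink count for interior
events.

## Content-aware classification

Positive class: land counters, predicted when the land-minus-water metric
falls *below* threshold (land counters suppress during land scenes).
Thresholds sweep all midpoints between sorted unique metrics plus sentinels
beyond both extremes; AUC is the trapezoid under the empirical ROC, which
equals the rank-sum (pairwise concordance, ties = ½) statistic — asserted
against an exhaustive pair-count oracle and scikit-learn's implementation.
The operating threshold maximizes Youden's J, ties resolved toward the
threshold nearest zero (the natural null point of a difference metric).
Confidence intervals are exact Clopper–Pearson via beta quantiles.  The
published sensitivity/specificity CIs (67.9–100%, 70.0–100%) match no
standard binomial interval we can identify — Clopper–Pearson at 11/11 and
10/10 gives 71.5–100% and 69.2–100% — so the CI method is a documented
choice here, and those printed bounds are not treated as a reproduction
target.

## Content-unaware classification

Linear soft-margin SVM on standardized interval-BPM vectors, leave-one-out
cross-validation.  Per fold: a seeded, stratified 75/25 split of the
training set selects C from a decade grid 10⁻²…10¹⁰ (13 values; the
published account gives only the range — grid and split are configurable;
stratification is our choice, since unstratified splits can orphan a class
at n = 21, and a single seeded split is used per fold); ties go to the
smallest C (strongest regularization, determinism + parsimony).  The best C
refits on the full training set to predict the left-out participant.
Standardization statistics always come from the rows being trained on —
never the left-out row — and a mutation test enforces this.

Training uses scikit-learn's libsvm solver through a thin low-level wrapper
(the public estimator's per-call overhead dominates at 20-row problems and
would make permutation calibration at scale impractical); a property test
asserts prediction equality with `SVC(kernel="linear")` across random
instances.  An iteration cap of 10⁶ guards pathological non-separable
fits at extreme C.

The permutation test reassigns parity labels without replacement and reruns
the *entire* LOOCV per iteration (1000 by default); the 95th percentile of
the null accuracies is the significance cutoff, and the p-value uses the
add-one estimator (1 + #{null ≥ observed})/(n_perm + 1), which cannot return
zero.  Note a known property of LOOCV nulls: accuracies center slightly
*below* the majority-class rate (removing a class member tilts the training
majority the other way), so null means near 50% rather than 52.4% at 11/10
are expected, and the calibration tests check the rejection rate, not the
null mean, against nominal.

## Classification strength

Per condition, each group's metric sample is summarized by a 1-D Gaussian
KDE with an absolute bandwidth (Silverman's rule 0.9·min(sd, IQR/1.34)·n^(−1/5)
by default; any positive override allowed).  The KDE is implemented directly
(mean of Gaussian kernels) because the semantics required — absolute
bandwidth, defined even for a single-point sample — do not match
covariance-factor KDE implementations; scipy's estimator serves as a
numerical cross-check where both are defined.  Likelihood ratios divide the
correct-group density at the participant's metric by the incorrect-group
density, both floored at 10⁻¹² (an LR of exactly 1 signals both densities
floored, i.e. the metric is an outlier to both groups).  By default the
participant's own metric is excluded from their group's density
(anti-circularity; published procedure silent on this), with an inclusive
mode for sensitivity analysis; a swap mode exchanges numerator and
denominator and negates log LR exactly.  Densities are per-condition, as
implied by the per-scene-duration analysis structure.

The regression suite fits log LR on the participant's within-condition
session BPM: polynomials of degree 1–3 by least squares with overall-F
p-values, and y = a·exp(bx) by nonlinear least squares initialized from a
log-linear fit when all y are positive (else from (mean(y), 0)); a
non-convergent exponential is recorded as failed with NA p, never silently
replaced.  Bonferroni correction multiplies p by 13 (the condition count).
The Deming fit uses the closed-form errors-in-variables estimator with
error-variance ratio 1 (orthogonal regression) by default — the published
supplement's ratio is unstated.

## Group statistics

The overall-rate comparison is the pooled-variance two-sample t (df 19 at
n = 21).  With a two-level within factor, the mixed-ANOVA scene×group
interaction is algebraically F = t² for the two-sample t on the
within-participant differences; both the t route and the direct
sums-of-squares route are computed and asserted equal to 10⁻⁹, and the
result is cross-checked against pingouin's mixed ANOVA in the tests
(balanced and unbalanced designs).  A degenerate design with zero
scene×subject error variance returns F = 0 when the interaction sum of
squares is also zero.  Per-timescale paired t-tests are Holm-corrected;
zero-variance conditions are skipped with NA and logged, and the Holm family
is the set of testable conditions.

## Problem sizes and numerical choices

Test and acceptance problem sizes are chosen to make the checked properties
near-deterministic while keeping the suite fast: realized-rate oracles use
10⁴ simulated minutes (3-SE bands); generator calibration uses 10⁴ draws
(±0.2 bpm at a population SD of 6.7 gives ≈3 SE headroom); the
content-unaware sweep uses 20 replicate cohorts × 10 interval sizes;
permutation-test type-I calibration uses 200 replicate cohorts of 15
participants over two videos with 199 permutations and a 5-value C grid
(the calibration property is exchangeability-based and independent of
cohort size or grid resolution); Holm family-wise error uses 200 full-size
null cohorts.  Float comparisons in I/O are exact (floats are written with
`repr`); AUC/concordance agreement is asserted to 10⁻¹²; the F = t² identity
to 10⁻⁹; KDE normalization to 10⁻⁶.

## Known limitations

- The detector's thresholds are validated only against the package's own
  renderer; real traces (pupil foreshortening from gaze angle, partial
  occlusions, camera dropouts) will need re-tuning, and the published
  real-data agreement figures cannot be reproduced here.
- The generator's instantaneous intensity switch at scene boundaries ignores
  blink-latency dynamics, overstating what is recoverable at 1 s scenes.
- Likelihood ratios are undefined in a strict sense when both densities
  floor; they are reported as 1 (no evidence either way) rather than NA.
- The mixed-ANOVA machinery covers only the study's 2×2 design, by intent.
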