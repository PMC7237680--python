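"""Classification strength via kernel-density likelihood ratios.

For each scene-duration condition, the content-aware metric (land-minus-water
bpm in that condition's video) of each experimental group is summarized by a
Gaussian kernel density estimate.  A participant's classification strength is
the likelihood ratio

    LR = p(metric | correct group) / p(metric | incorrect group),

with LR > 1 meaning the participant's metric is more probable under their own
group's distribution.  By default the participant's own metric is left out of
their correct group's density (anti-circularity); an inclusive mode exists
for sensitivity checks.  A regression suite (linear/quadratic/cubic
polynomials and an exponential) then relates log(LR) to individual blink
rate, with Bonferroni correction over the 13 conditions; a Deming
(errors-in-variables) fit backs the linear result.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats

from .types import ValidationError


# ---------------------------------------------------------------------------
# 1-D Gaussian KDE with an absolute bandwidth


class GaussianKDE1D:
    """Mean of Gaussian kernels with an absolute (data-unit) bandwidth.

    Bandwidth defaults to Silverman's rule
    ``0.9 * min(sd, IQR/1.34) * n**(-1/5)``; it may be overridden with any
    positive value, including for a single-point sample.  The density
    integrates to 1 by construction.
    """

    def __init__(self, values: Sequence[float], bandwidth: Optional[float] = None):
        self.values = np.asarray(values, dtype=float)
        if self.values.ndim != 1 or len(self.values) == 0:
            raise ValidationError("KDE needs a non-empty 1-D sample")
        if bandwidth is None:
            bandwidth = silverman_bandwidth(self.values)
        if not bandwidth > 0:
            raise ValidationError(
                "zero KDE bandwidth (identical values?); supply one explicitly"
            )
        self.bandwidth = float(bandwidth)

    def __call__(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        z = (x[..., None] - self.values) / self.bandwidth
        dens = np.exp(-0.5 * z**2).sum(axis=-1)
        dens /= len(self.values) * self.bandwidth * math.sqrt(2 * math.pi)
        return dens


def silverman_bandwidth(values: np.ndarray) -> float:
    values = np.asarray(values, dtype=float)
    n = len(values)
    sd = float(np.std(values, ddof=1)) if n > 1 else 0.0
    iqr = float(np.subtract(*np.percentile(values, [75, 25])))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    return 0.9 * spread * n ** (-0.2)


def group_pdf(
    metrics: Sequence[float], bandwidth: Optional[float] = None
) -> GaussianKDE1D:
    """Density of one group's classification metrics."""
    metrics = np.asarray(metrics, dtype=float)
    if len(metrics) < 2 and bandwidth is None:
        raise ValidationError("group_pdf needs >= 2 values (or a forced bandwidth)")
    return GaussianKDE1D(metrics, bandwidth)


# ---------------------------------------------------------------------------
# Likelihood ratios


@dataclass
class LikelihoodResult:
    participant_id: str
    condition_s: float
    metric: float
    lr: float
    log_lr: float


def likelihood_ratio(
    metric: float,
    pdf_correct,
    pdf_incorrect,
    floor: float = 1e-12,
    participant_id: str = "",
    condition_s: float = float("nan"),
) -> LikelihoodResult:
    """LR of one metric under two densities; a floor guards zero densities."""
    p_c = max(float(pdf_correct(metric)), floor)
    p_i = max(float(pdf_incorrect(metric)), floor)
    lr = p_c / p_i
    return LikelihoodResult(
        participant_id=participant_id,
        condition_s=condition_s,
        metric=float(metric),
        lr=lr,
        log_lr=math.log(lr),
    )


def cohort_likelihoods(
    participant_ids: Sequence[str],
    metrics: Sequence[float],
    groups: Sequence[str],
    condition_s: float = float("nan"),
    bandwidth: Optional[float] = None,
    leave_one_out: bool = True,
    floor: float = 1e-12,
    swap_groups: bool = False,
) -> List[LikelihoodResult]:
    """Likelihood ratios for every participant in a condition.

    Each participant's correct-group density excludes their own metric when
    ``leave_one_out`` (the default), so a participant never certifies their
    own group fit.  Exclusion applies to the participant's own group sample
    wherever it appears, which makes ``swap_groups`` (a sensitivity mode that
    exchanges the correct and incorrect densities) negate log(LR) exactly.
    """
    metrics = np.asarray(metrics, dtype=float)
    groups = np.asarray(groups)
    uniq = sorted(set(groups))
    if len(uniq) != 2:
        raise ValidationError(f"need exactly 2 groups, got {uniq}")
    results = []
    for i, pid in enumerate(participant_ids):
        own, other = groups[i], uniq[1 - uniq.index(groups[i])]
        own_sample = metrics[(groups == own)]
        if leave_one_out:
            mask = np.ones(len(metrics), dtype=bool)
            mask[i] = False
            own_sample = metrics[(groups == own) & mask]
        other_sample = metrics[groups == other]
        if len(own_sample) == 0 or len(other_sample) == 0:
            raise ValidationError(f"participant {pid}: empty group sample")
        pdf_own = GaussianKDE1D(own_sample, bandwidth)
        pdf_other = GaussianKDE1D(other_sample, bandwidth)
        pdf_num, pdf_den = (
            (pdf_other, pdf_own) if swap_groups else (pdf_own, pdf_other)
        )
        results.append(
            likelihood_ratio(
                metrics[i],
                pdf_num,
                pdf_den,
                floor=floor,
                participant_id=pid,
                condition_s=condition_s,
            )
        )
    return results


# ---------------------------------------------------------------------------
# Regression suite


@dataclass
class RegressionFit:
    condition_s: float
    form: str  # linear | quadratic | cubic | exponential
    coefficients: Tuple[float, ...]
    r_squared: float
    p_value: float
    p_bonferroni: float
    converged: bool = True


def _overall_f_p(y: np.ndarray, resid: np.ndarray, n_params: int) -> float:
    """Two-sided p for the overall fit: F-test against the constant model."""
    n = len(y)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    ss_res = float(np.sum(resid**2))
    df1 = n_params - 1
    df2 = n - n_params
    if df2 <= 0 or ss_tot <= 0:
        return float("nan")
    if ss_res <= 0:
        return 0.0
    f = ((ss_tot - ss_res) / df1) / (ss_res / df2)
    return float(stats.f.sf(f, df1, df2))


def strength_regressions(
    x: Sequence[float],
    y: Sequence[float],
    condition_s: float = float("nan"),
    n_comparisons: int = 13,
) -> List[RegressionFit]:
    """Polynomial (degree 1-3) and exponential fits of y on x.

    The exponential model is ``y = a * exp(b * x)`` by nonlinear least
    squares, initialized from a log-linear fit when all y are positive, else
    from ``(mean(y), 0)``.  A non-convergent exponential fit is recorded as
    failed with NA p, never silently replaced by a polynomial.  Bonferroni
    correction multiplies p by ``n_comparisons``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(x) == 0:
        raise ValidationError("constant x: singular design")
    fits: List[RegressionFit] = []
    ss_tot = float(np.sum((y - y.mean()) ** 2))

    for degree, form in ((1, "linear"), (2, "quadratic"), (3, "cubic")):
        if len(x) < max(5, degree + 2):
            raise ValidationError(f"too few points for {form} fit")
        coefs = np.polyfit(x, y, degree)
        resid = y - np.polyval(coefs, x)
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
        p = _overall_f_p(y, resid, degree + 1)
        fits.append(
            RegressionFit(
                condition_s=condition_s,
                form=form,
                coefficients=tuple(coefs[::-1]),  # ascending order
                r_squared=min(max(r2, 0.0), 1.0),
                p_value=p,
                p_bonferroni=min(1.0, n_comparisons * p) if np.isfinite(p) else float("nan"),
            )
        )

    if np.all(y > 0):
        b0, log_a0 = np.polyfit(x, np.log(y), 1)
        p0 = (math.exp(log_a0), b0)
    else:
        p0 = (float(np.mean(y)), 0.0)
    try:
        popt, _ = optimize.curve_fit(
            lambda t, a, b: a * np.exp(b * t), x, y, p0=p0, maxfev=10000
        )
        resid = y - popt[0] * np.exp(popt[1] * x)
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
        p = _overall_f_p(y, resid, 2)
        fits.append(
            RegressionFit(
                condition_s=condition_s,
                form="exponential",
                coefficients=(float(popt[0]), float(popt[1])),
                r_squared=min(max(r2, 0.0), 1.0),
                p_value=p,
                p_bonferroni=min(1.0, n_comparisons * p) if np.isfinite(p) else float("nan"),
            )
        )
    except RuntimeError:
        fits.append(
            RegressionFit(
                condition_s=condition_s,
                form="exponential",
                coefficients=(float("nan"), float("nan")),
                r_squared=float("nan"),
                p_value=float("nan"),
                p_bonferroni=float("nan"),
                converged=False,
            )
        )
    return fits


def deming_fit(
    x: Sequence[float], y: Sequence[float], variance_ratio: float = 1.0
) -> Tuple[float, float]:
    """Deming (errors-in-variables) line fit, closed form.

    ``variance_ratio`` is the ratio of the y- to x-measurement error
    variances; 1 gives orthogonal regression.  Returns (slope, intercept).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(x) != len(y):
        raise ValidationError("deming_fit needs >= 3 paired points")
    if variance_ratio <= 0:
        raise ValidationError("variance_ratio must be > 0")
    sxx = float(np.var(x, ddof=1))
    syy = float(np.var(y, ddof=1))
    sxy = float(np.cov(x, y, ddof=1)[0, 1])
    if sxx == 0 and syy == 0:
        raise ValidationError("zero variance in both axes")
    d = variance_ratio
    if sxy == 0:
        raise ValidationError("zero covariance: slope undefined for Deming fit")
    slope = (syy - d * sxx + math.sqrt((syy - d * sxx) ** 2 + 4 * d * sxy**2)) / (
        2 * sxy
    )
    intercept = float(np.mean(y) - slope * np.mean(x))
    return slope, intercept
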