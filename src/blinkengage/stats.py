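"""Inferential statistics for the two-task blink-rate design.

Covers the study's test battery: Shapiro-Wilk normality checks, the pooled
two-sample t on overall rates, the scene-type x task-group interaction from
the 2 (within) x 2 (between) mixed design, and per-timescale paired t-tests
with Bonferroni-Holm step-down correction.

With a two-level within-subject factor the mixed-ANOVA interaction reduces
exactly to a two-sample t-test on the within-participant differences
(F = t^2, df = (1, n-2)); both routes are computed and asserted equal rather
than delegating to a general mixed-model engine.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class StatTestResult:
    test_name: str
    statistic: float
    df: Tuple[float, ...]
    p_value: float
    n: int
    p_corrected: Optional[float] = None
    condition_s: Optional[float] = None


def normality_check(values: Sequence[float], name: str = "shapiro") -> StatTestResult:
    """Shapiro-Wilk test of normality."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    if not 3 <= n <= 5000:
        raise ValidationError(f"Shapiro-Wilk needs 3 <= n <= 5000, got {n}")
    if np.ptp(values) == 0:
        raise ValidationError("constant input: normality test undefined")
    w, p = stats.shapiro(values)
    return StatTestResult(
        test_name=name, statistic=float(w), df=(float(n - 2),), p_value=float(p), n=n
    )


def two_sample_t(
    a: Sequence[float], b: Sequence[float], name: str = "two_sample_t"
) -> StatTestResult:
    """Pooled-variance two-sample t-test (df = n1 + n2 - 2)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    t, p = stats.ttest_ind(a, b, equal_var=True)
    df = len(a) + len(b) - 2
    return StatTestResult(
        test_name=name,
        statistic=float(t),
        df=(float(df),),
        p_value=float(p),
        n=len(a) + len(b),
    )


def paired_t(
    x: Sequence[float], y: Sequence[float], name: str = "paired_t"
) -> StatTestResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValidationError("paired test needs complete pairs")
    t, p = stats.ttest_rel(x, y)
    return StatTestResult(
        test_name=name,
        statistic=float(t),
        df=(float(len(x) - 1),),
        p_value=float(p),
        n=len(x),
    )


def interaction_anova(
    bpm_land: Sequence[float],
    bpm_water: Sequence[float],
    groups: Sequence[str],
) -> StatTestResult:
    """Scene-type x group interaction of the 2x2 mixed design.

    Computed two ways — as the squared pooled two-sample t on the
    within-participant (land - water) differences, and from the mixed-model
    sums of squares directly — and the two are asserted equal.
    """
    land = np.asarray(bpm_land, dtype=float)
    water = np.asarray(bpm_water, dtype=float)
    groups = np.asarray(groups)
    if not (len(land) == len(water) == len(groups)):
        raise ValidationError("incomplete pairs in interaction design")
    uniq = sorted(set(groups))
    if len(uniq) != 2:
        raise ValidationError(f"need exactly 2 groups, got {uniq}")
    g0, g1 = (groups == uniq[0], groups == uniq[1])
    if g0.sum() < 2 or g1.sum() < 2:
        raise ValidationError("each group needs >= 2 participants")

    diff = land - water
    t_res = two_sample_t(diff[g0], diff[g1])
    f_from_t = t_res.statistic**2

    # direct sums-of-squares route: interaction and scene-x-subject error
    half = diff / 2.0  # subject's scene contrast on the cell-mean scale
    n0, n1 = int(g0.sum()), int(g1.sum())
    grand = half.mean()  # grand contrast, weighted by group size
    ss_int = 2.0 * (
        n0 * (half[g0].mean() - grand) ** 2 + n1 * (half[g1].mean() - grand) ** 2
    )
    ss_err = 2.0 * (
        np.sum((half[g0] - half[g0].mean()) ** 2)
        + np.sum((half[g1] - half[g1].mean()) ** 2)
    )
    df_err = n0 + n1 - 2
    if ss_err > 0:
        f_direct = ss_int / (ss_err / df_err)
        if abs(f_direct - f_from_t) > 1e-9 * max(1.0, abs(f_from_t)):
            raise AssertionError(
                f"interaction F routes disagree: {f_direct} vs {f_from_t}"
            )
    else:
        # degenerate design: zero scene-x-subject error variance
        f_from_t = 0.0 if ss_int <= 1e-18 else float("inf")

    p = float(stats.f.sf(f_from_t, 1, df_err)) if np.isfinite(f_from_t) else 0.0
    return StatTestResult(
        test_name="scene_x_group_interaction",
        statistic=float(f_from_t),
        df=(1.0, float(df_err)),
        p_value=p,
        n=n0 + n1,
    )


def holm_correction(p_values: Sequence[float]) -> np.ndarray:
    """Bonferroni-Holm step-down adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    _, p_adj, _, _ = multipletests(p, method="holm")
    return p_adj


def timescale_paired_tests(
    relevant_by_condition: Dict[float, Sequence[float]],
    irrelevant_by_condition: Dict[float, Sequence[float]],
) -> List[StatTestResult]:
    """Paired t of relevant vs irrelevant bpm per condition, Holm-corrected.

    Conditions with zero-variance differences are skipped with NA and logged;
    the Holm family is the set of testable conditions.
    """
    results: List[StatTestResult] = []
    testable: List[StatTestResult] = []
    for cond in sorted(relevant_by_condition):
        rel = np.asarray(relevant_by_condition[cond], dtype=float)
        irr = np.asarray(irrelevant_by_condition[cond], dtype=float)
        if len(rel) != len(irr):
            raise ValidationError(f"condition {cond}: incomplete pairs")
        if np.ptp(rel - irr) == 0:
            logger.warning("condition %s: zero-variance differences, skipped", cond)
            results.append(
                StatTestResult(
                    test_name="paired_t_relevant_vs_irrelevant",
                    statistic=float("nan"),
                    df=(float(len(rel) - 1),),
                    p_value=float("nan"),
                    n=len(rel),
                    condition_s=cond,
                )
            )
            continue
        res = paired_t(rel, irr, name="paired_t_relevant_vs_irrelevant")
        res.condition_s = cond
        results.append(res)
        testable.append(res)
    if testable:
        adj = holm_correction([r.p_value for r in testable])
        for r, a in zip(testable, adj):
            r.p_corrected = float(a)
    return results
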