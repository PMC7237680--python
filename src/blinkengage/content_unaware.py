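"""Content-unaware classification of attended-scene parity.

Feature vectors are interval-averaged blink rates concatenated across all
composite videos — no knowledge of scene categories or timing enters the
features.  Labels are the counterbalancing parity ("attended_odd" /
"attended_even": whether task-relevant scenes occupied odd or even positions).

A linear soft-margin SVM is trained and evaluated by leave-one-out
cross-validation.  Within each fold, the regularization parameter C is chosen
by an inner split: for each candidate C the model is trained on 75% of the
training set and scored on the remaining 25%; the best C (ties going to the
smallest, i.e. strongest regularization) is refit on the whole training set
to predict the left-out participant.  Feature standardization always uses
statistics of the rows being trained on, never the left-out row.

Statistical significance of the observed accuracy is assessed by permuting
the parity labels without replacement and re-running the entire
cross-validation per permutation; the add-one estimator
``p = (1 + #{null >= observed}) / (n_perm + 1)`` avoids p = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from ._svm import fit_linear_svm, predict_linear_svm
from .rates import interval_vector
from .types import (
    PARITY_EVEN,
    PARITY_ODD,
    ParticipantRecord,
    SceneSchedule,
    ValidationError,
)

DEFAULT_C_GRID = tuple(10.0 ** k for k in range(-2, 11))  # 10^-2 .. 10^10


@dataclass(frozen=True)
class SVMConfig:
    c_grid: Tuple[float, ...] = DEFAULT_C_GRID
    inner_train_frac: float = 0.75
    standardize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        grid = np.asarray(self.c_grid)
        if len(grid) == 0 or np.any(grid <= 0) or np.any(np.diff(grid) <= 0):
            raise ValidationError("c_grid must be strictly increasing and positive")
        if not 0 < self.inner_train_frac < 1:
            raise ValidationError("inner_train_frac must be in (0, 1)")


@dataclass
class ClassifierReport:
    interval_s: Optional[float]
    participant_ids: List[str]
    y_true: List[str]
    y_pred: List[str]
    n_correct: int
    percent_correct: float
    chosen_c: List[float]
    null_accuracies: Optional[np.ndarray] = None
    cutoff_95: Optional[float] = None
    p_value: Optional[float] = None


@dataclass
class FeatureSet:
    X: np.ndarray  # participants x concatenated interval bins, bpm
    labels: np.ndarray  # parity strings
    participant_ids: List[str]
    interval_s: float


def build_features(
    records: Sequence[ParticipantRecord],
    schedules: Mapping[str, SceneSchedule],
    interval_s: float,
) -> FeatureSet:
    """One feature row per participant, in input order.

    All participants must produce profiles of equal length (same bin layout);
    a mismatch names the offending participant.
    """
    rows, ids, labels = [], [], []
    length = None
    for rec in records:
        profile = interval_vector(rec, schedules, interval_s)
        if length is None:
            length = len(profile)
        elif len(profile) != length:
            raise ValidationError(
                f"participant {rec.participant_id}: feature length "
                f"{len(profile)} != {length}"
            )
        rows.append(profile.values)
        ids.append(rec.participant_id)
        labels.append(rec.parity)
    if not rows:
        raise ValidationError("no participants")
    return FeatureSet(
        X=np.vstack(rows),
        labels=np.asarray(labels),
        participant_ids=ids,
        interval_s=float(interval_s),
    )


def _standardize(X_fit: np.ndarray, *apply_to: np.ndarray) -> List[np.ndarray]:
    mean = X_fit.mean(axis=0)
    sd = X_fit.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return [(A - mean) / sd for A in apply_to]


def _inner_split(
    y01: np.ndarray, train_frac: float, rng: np.random.Generator
) -> Tuple[np.ndarray, np.ndarray]:
    """Stratified split of training rows into (fit, eval) index arrays.

    Redraws (up to 100 times) if either side would lose a class entirely;
    with fewer than two members of a class no valid split exists.
    """
    n = len(y01)
    for _ in range(100):
        fit_idx, eval_idx = [], []
        for cls in (0, 1):
            members = np.flatnonzero(y01 == cls)
            perm = rng.permutation(members)
            n_fit = int(round(train_frac * len(members)))
            n_fit = min(max(n_fit, 1), len(members) - 1) if len(members) > 1 else n_fit
            fit_idx.append(perm[:n_fit])
            eval_idx.append(perm[n_fit:])
        fit_idx = np.concatenate(fit_idx)
        eval_idx = np.concatenate(eval_idx)
        if len(set(y01[fit_idx])) == 2 and len(set(y01[eval_idx])) == 2:
            return np.sort(fit_idx), np.sort(eval_idx)
    raise ValidationError(
        "inner split cannot keep both classes on both sides "
        "(a class has fewer than 2 training members)"
    )


def _loocv_accuracy(
    X: np.ndarray, y01: np.ndarray, config: SVMConfig, rng: np.random.Generator
) -> Tuple[np.ndarray, List[float]]:
    """Core LOOCV loop on 0/1 codes.  Returns (predictions, chosen C per fold)."""
    n = len(y01)
    preds = np.empty(n, dtype=int)
    chosen: List[float] = []
    for i in range(n):
        train = np.concatenate([np.arange(i), np.arange(i + 1, n)])
        y_tr = y01[train]
        if min(np.count_nonzero(y_tr == 0), np.count_nonzero(y_tr == 1)) < 2:
            raise ValidationError("need at least 2 training members per class")
        X_tr = X[train]
        fit_idx, eval_idx = _inner_split(y_tr, config.inner_train_frac, rng)
        X_fit, X_eval = X_tr[fit_idx], X_tr[eval_idx]
        if config.standardize:
            X_fit, X_eval = _standardize(X_fit, X_fit, X_eval)
        y_fit, y_eval = y_tr[fit_idx], y_tr[eval_idx]

        best_c, best_acc = None, -1.0
        for C in config.c_grid:  # ascending: ties keep the smallest C
            w, b = fit_linear_svm(X_fit, y_fit, C)
            acc = float(np.mean(predict_linear_svm(X_eval, w, b) == y_eval))
            if acc > best_acc:
                best_c, best_acc = C, acc
        chosen.append(best_c)

        X_left = X[i : i + 1]
        if config.standardize:
            X_tr_s, X_left = _standardize(X_tr, X_tr, X_left)
        else:
            X_tr_s = X_tr
        w, b = fit_linear_svm(X_tr_s, y_tr, best_c)
        preds[i] = predict_linear_svm(X_left, w, b)[0]
    return preds, chosen


def _encode(labels: np.ndarray) -> np.ndarray:
    known = {PARITY_ODD, PARITY_EVEN}
    if not set(labels) <= known:
        raise ValidationError(f"unknown parity labels: {set(labels) - known}")
    return (labels == PARITY_ODD).astype(int)


def loocv_classify(
    features: FeatureSet, config: Optional[SVMConfig] = None
) -> ClassifierReport:
    """Leave-one-out classification of parity labels.

    Reproducible: the same config seed yields identical inner splits, chosen
    C values, and fold predictions.
    """
    config = config or SVMConfig()
    y01 = _encode(features.labels)
    if min(np.count_nonzero(y01 == 0), np.count_nonzero(y01 == 1)) < 2:
        raise ValidationError("need at least 2 participants per parity label")
    rng = np.random.default_rng(config.seed)
    preds, chosen = _loocv_accuracy(features.X, y01, config, rng)
    decode = np.array([PARITY_EVEN, PARITY_ODD])
    y_pred = decode[preds]
    n_correct = int(np.sum(preds == y01))
    return ClassifierReport(
        interval_s=features.interval_s,
        participant_ids=list(features.participant_ids),
        y_true=list(features.labels),
        y_pred=list(y_pred),
        n_correct=n_correct,
        percent_correct=100.0 * n_correct / len(y01),
        chosen_c=chosen,
    )


def permutation_test(
    features: FeatureSet,
    config: Optional[SVMConfig] = None,
    n_perm: int = 1000,
    perm_seed: Optional[int] = None,
) -> ClassifierReport:
    """Observed LOOCV accuracy against a label-permutation null.

    Each iteration reassigns the parity labels without replacement and reruns
    the full cross-validation.  ``cutoff_95`` is the empirical 95th percentile
    of the null accuracies; the p-value uses the add-one estimator.
    """
    if n_perm < 100:
        raise ValidationError("n_perm must be >= 100")
    config = config or SVMConfig()
    report = loocv_classify(features, config)
    y01 = _encode(features.labels)
    rng = np.random.default_rng(config.seed if perm_seed is None else perm_seed)
    null = np.empty(n_perm)
    for it in range(n_perm):
        y_perm = rng.permutation(y01)
        inner_rng = np.random.default_rng(config.seed)
        preds, _ = _loocv_accuracy(features.X, y_perm, config, inner_rng)
        null[it] = 100.0 * np.mean(preds == y_perm)
    report.null_accuracies = null
    report.cutoff_95 = float(np.quantile(null, 0.95, method="higher"))
    report.p_value = float(
        (1 + np.count_nonzero(null >= report.percent_correct)) / (n_perm + 1)
    )
    return report
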