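"""Minimal linear soft-margin SVM fit, tuned for very small samples.

The leave-one-out + permutation machinery needs millions of SVM fits on
samples of ~20 rows.  The public ``sklearn.svm.SVC`` estimator carries
per-call validation overhead that dominates at this size, so this module
calls scikit-learn's bundled libsvm solver directly.  The result is the same
C-SVC optimum; a property test asserts prediction equality with
``SVC(kernel="linear")`` on random instances.  If the low-level entry point
is unavailable, the public estimator is used transparently.
"""

from __future__ import annotations

from typing import Tuple

import numpy as np

try:  # scikit-learn's internal libsvm binding (stable across 1.x)
    from sklearn.svm import _libsvm

    _libsvm.set_verbosity_wrap(0)
    _HAVE_LIBSVM = True
except Exception:  # pragma: no cover - fallback path
    _libsvm = None
    _HAVE_LIBSVM = False

from sklearn.svm import SVC

#: Iteration cap; hit only for extreme C on non-separable data, where the
#: truncated solution is still a usable (and deterministic) candidate.
MAX_ITER = 1_000_000


def fit_linear_svm(X: np.ndarray, y01: np.ndarray, C: float) -> Tuple[np.ndarray, float]:
    """Fit a two-class linear C-SVM.

    ``y01`` holds 0/1 class codes.  Returns ``(w, b)`` such that
    ``x @ w + b > 0`` predicts class 1.
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.ascontiguousarray(y01, dtype=np.float64)
    if _HAVE_LIBSVM:
        out = _libsvm.fit(
            X,
            y,
            svm_type=0,
            kernel="linear",
            C=float(C),
            tol=1e-3,
            max_iter=MAX_ITER,
        )
        support_vectors, sv_coef, intercept = out[1], out[3], out[4]
        w = (sv_coef @ support_vectors).ravel()
        b = float(intercept[0])
        # libsvm's raw decision function is positive on the class-0 side for
        # 0/1-coded labels; negate so positive predicts class 1
        return -w, -b
    svc = SVC(kernel="linear", C=float(C), max_iter=MAX_ITER).fit(X, y)
    return svc.coef_.ravel().copy(), float(svc.intercept_[0])


def predict_linear_svm(X: np.ndarray, w: np.ndarray, b: float) -> np.ndarray:
    """0/1 predictions for the decision function ``x @ w + b``."""
    return (X @ w + b > 0).astype(int)
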