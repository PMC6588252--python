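"""Fast binary RBF-SVM fit/predict for the forward-selection inner loop.

Forward selection scores thousands of tiny candidate models per fold; the
public ``SVC`` estimator spends most of that time in Python-level
validation.  When available, scikit-learn's low-level libsvm binding is
called directly — it is the very solver ``SVC`` wraps and produces
identical predictions (asserted in the test suite) — with a transparent
fallback to ``SVC`` otherwise.  All *final* models in the pipeline are
ordinary ``SVC`` instances.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly everywhere
    from sklearn.svm import _libsvm as _impl

    _impl.set_verbosity_wrap(0)
    _HAVE_LIBSVM = True
except Exception:  # pragma: no cover
    _impl = None
    _HAVE_LIBSVM = False

from sklearn.svm import SVC


def fit_predict(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    C: float,
    gamma: float,
) -> np.ndarray:
    """Train a binary C-SVC with an RBF kernel and predict ``X_test``.

    ``y_train`` must be float64 0/1 labels; returns float64 predictions.
    """
    if _HAVE_LIBSVM:
        Xtr = np.ascontiguousarray(X_train, dtype=np.float64)
        Xte = np.ascontiguousarray(X_test, dtype=np.float64)
        ytr = np.ascontiguousarray(y_train, dtype=np.float64)
        out = _impl.fit(Xtr, ytr, svm_type=0, kernel="rbf", C=C, gamma=gamma)
        return _impl.predict(
            Xte, out[0], out[1], out[2], out[3], out[4], out[5], out[6],
            svm_type=0, kernel="rbf", gamma=gamma,
        )
    model = SVC(C=C, kernel="rbf", gamma=gamma)
    model.fit(X_train, y_train)
    return model.predict(X_test).astype(np.float64)
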