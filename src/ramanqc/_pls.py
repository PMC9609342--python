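"""Thin PLS utilities shared by the variable selectors and the PLSR engine.

Wraps scikit-learn's NIPALS PLS but exposes the *coefficient path*: the
regression vector truncated to every number of latent variables up to the
fitted maximum.  Because PLS deflation is sequential, the coefficient vector
for k components is sum_{j<=k} r_j q_j with r_j the X rotation columns and
q_j the y loadings, so one fit yields cross-validated errors for all
component counts.
"""

from __future__ import annotations

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import KFold

from .errors import DataError, DegenerateTargetError, ParameterError

MAX_COMPONENTS = 10


def _max_ncomp(n_samples: int, n_features: int, cap: int = MAX_COMPONENTS) -> int:
    return max(1, min(cap, n_samples - 1, n_features))


def pls_coefficient_paths(X: np.ndarray, y: np.ndarray, max_components: int
                          ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fit centered PLS once; return per-k coefficients.

    Returns ``(B, x_mean, y_mean)`` where ``B[k-1]`` is the coefficient
    vector using k latent variables: predictions are
    ``(X - x_mean) @ B[k-1] + y_mean``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise DataError(f"X rows ({X.shape[0]}) != y length ({y.size})")
    if np.ptp(y) == 0.0:
        raise DegenerateTargetError("constant target vector")
    k = _max_ncomp(X.shape[0], X.shape[1], max_components)
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    try:
        import warnings

        pls = PLSRegression(n_components=k, scale=False)
        with np.errstate(invalid="ignore", divide="ignore"), \
                warnings.catch_warnings():
            warnings.filterwarnings("ignore", message=".*residual is constant.*")
            pls.fit(X - x_mean, y - y_mean)
        R = pls.x_rotations_            # (p, k)
        Q = pls.y_loadings_.ravel()     # (k,)
        # cumulative sum of rank-1 terms r_j * q_j
        B = np.cumsum(R * Q[np.newaxis, :], axis=1).T  # (k, p)
        B = np.nan_to_num(B, nan=0.0, posinf=0.0, neginf=0.0)
    except (ValueError, np.linalg.LinAlgError):
        # degenerate design (e.g. zero-variance X): predict the mean
        B = np.zeros((k, X.shape[1]))
    return B, x_mean, y_mean


def pls_fit_predictor(X: np.ndarray, y: np.ndarray, n_components: int):
    """Return (predict_fn, coef) for a centered PLS fit at a fixed k."""
    B, x_mean, y_mean = pls_coefficient_paths(X, y, n_components)
    coef = B[-1]

    def predict(Xnew: np.ndarray) -> np.ndarray:
        return (np.asarray(Xnew, dtype=float) - x_mean) @ coef + y_mean

    return predict, coef


def rmsecv_path(X: np.ndarray, y: np.ndarray, max_components: int = MAX_COMPONENTS,
                folds: int = 5, seed: int = 0) -> np.ndarray:
    """Pooled k-fold RMSECV for every component count 1..kmax (one array).

    Folds are shuffled once from ``seed``; each fold fits a single PLS and
    evaluates its whole coefficient path on the held-out block.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if folds < 2:
        raise ParameterError("folds must be >= 2")
    folds = min(folds, n)
    kmax = max(1, min(max_components, X.shape[1], n - (n + folds - 1) // folds - 1))
    press = np.zeros(kmax)
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    for train, test in kf.split(X):
        k_fold = min(kmax, len(train) - 1)
        B, x_mean, y_mean = pls_coefficient_paths(X[train], y[train], k_fold)
        preds = (X[test] - x_mean) @ B.T + y_mean      # (n_test, k_fold)
        if k_fold < kmax:  # reuse the largest available model for missing ks
            preds = np.hstack([preds,
                               np.repeat(preds[:, -1:], kmax - k_fold, axis=1)])
        press += np.sum((preds - y[test, np.newaxis]) ** 2, axis=0)
    return np.sqrt(press / n)


def best_ncomp(X: np.ndarray, y: np.ndarray, max_components: int = MAX_COMPONENTS,
               folds: int = 5, seed: int = 0) -> tuple[int, float]:
    """(component count with minimal RMSECV, that RMSECV)."""
    path = rmsecv_path(X, y, max_components, folds, seed)
    k = int(np.argmin(path))
    return k + 1, float(path[k])
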