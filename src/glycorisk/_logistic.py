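"""Small IRLS logistic-regression backend shared by the selection and ROC code.

Deliberately minimal: dense Newton/IRLS with a tiny ridge for numerical
stability (handles collinear and separable designs without crashing). Only
fitted probabilities are consumed downstream, never standard errors.
"""

from __future__ import annotations

import numpy as np

_CLIP = 35.0  # logit clip; exp(35) overflows nothing, probabilities saturate


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(eta, -_CLIP, _CLIP)))


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    *,
    ridge: float = 1e-8,
    max_iter: int = 50,
    tol: float = 1e-9,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Fit a logit-link binomial GLM with intercept.

    Parameters
    ----------
    X : (n, k) design without intercept column (k may be 0).
    y : (n,) 0/1 outcome.

    Returns
    -------
    beta : (k+1,) coefficients, intercept first.
    prob : (n,) fitted probabilities.
    separated : True when the fit ran into (quasi-)separation, detected by
        runaway coefficients.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = y.shape[0]
    X1 = np.column_stack([np.ones(n), X])
    beta = np.zeros(X1.shape[1])
    separated = False
    for _ in range(max_iter):
        p = _sigmoid(X1 @ beta)
        w = np.maximum(p * (1.0 - p), 1e-12)
        H = X1.T @ (X1 * w[:, None])
        H[np.diag_indices_from(H)] += ridge
        g = X1.T @ (y - p)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, g, rcond=None)[0]
        beta = beta + step
        if np.max(np.abs(beta)) > 1e4:
            separated = True
            break
        if np.max(np.abs(step)) < tol:
            break
    prob = _sigmoid(X1 @ beta)
    return beta, prob, separated


def predict_logistic(beta: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Probabilities for a new design given coefficients from fit_logistic."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    X1 = np.column_stack([np.ones(X.shape[0]), X])
    return _sigmoid(X1 @ beta)
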