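"""NIPALS PLS1 core and cross-validated RMSE path evaluation.

For a single response, NIPALS needs no inner iteration: each component's
weight vector is exactly ``X_deflated.T @ y_deflated`` (normalized), so a
fit costs a handful of matrix-vector products per latent variable.  The
batched variant evaluates many band subsets at once by zeroing excluded
columns of the *centered* training matrix — identical to fitting on the
column subset, because a zero column gets zero weight and zero loading
and never mixes into the scores.  Wavelength selectors lean on this to
score thousands of candidate subsets at BLAS speed.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "nipals_pls1",
    "pls1_predict_path",
    "kfold_indices",
    "cv_rmse_path",
    "cv_rmse_path_subsets",
]


def nipals_pls1(Xc: np.ndarray, yc: np.ndarray, n_lv: int):
    """NIPALS on centered data; returns (W, P, q, T).

    W, P are p x k weight/loading matrices, q the length-k response
    loadings, T the n x k score matrix.  Extraction stops early (zero
    padding) if X deflates to numerical rank exhaustion.
    """
    Xd = Xc.copy()
    yd = yc.copy()
    n, p = Xd.shape
    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    q = np.zeros(n_lv)
    T = np.zeros((n, n_lv))
    for k in range(n_lv):
        w = Xd.T @ yd
        norm = np.linalg.norm(w)
        if norm <= 1e-13:
            break
        w /= norm
        t = Xd @ w
        tt = float(t @ t)
        if tt <= 1e-26:
            break
        p_load = Xd.T @ t / tt
        qk = float(yd @ t) / tt
        Xd -= np.outer(t, p_load)
        yd -= qk * t
        W[:, k] = w
        P[:, k] = p_load
        q[k] = qk
        T[:, k] = t
    return W, P, q, T


def pls1_predict_path(Xc_new: np.ndarray, W: np.ndarray, P: np.ndarray, q: np.ndarray):
    """Predicted centered responses after 1..k components (n x k)."""
    r = Xc_new.copy()
    n, k = Xc_new.shape[0], W.shape[1]
    path = np.zeros((n, k))
    acc = np.zeros(n)
    for j in range(k):
        t = r @ W[:, j]
        r -= np.outer(t, P[:, j])
        acc = acc + q[j] * t
        path[:, j] = acc
    return path


def kfold_indices(n: int, n_folds: int, rng: np.random.Generator | None = None):
    """Deterministic shuffled k-fold partition; list of test-index arrays."""
    order = np.arange(n) if rng is None else rng.permutation(n)
    return [order[i::n_folds] for i in range(n_folds)]


def cv_rmse_path(
    X: np.ndarray,
    y: np.ndarray,
    max_lv: int,
    folds: list[np.ndarray],
) -> np.ndarray:
    """k-fold cross-validated RMSE after 1..max_lv components.

    Pooled out-of-fold squared errors; X and y are centered per training
    fold.  Returns an array of length max_lv.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    max_lv = int(min(max_lv, p, n - max(len(f) for f in folds) - 1))
    max_lv = max(max_lv, 1)
    sse = np.zeros(max_lv)
    for test in folds:
        train = np.setdiff1d(np.arange(n), test, assume_unique=False)
        x_mean = X[train].mean(axis=0)
        y_mean = y[train].mean()
        W, P, q, _ = nipals_pls1(X[train] - x_mean, y[train] - y_mean, max_lv)
        path = pls1_predict_path(X[test] - x_mean, W, P, q) + y_mean
        sse += ((y[test][:, None] - path) ** 2).sum(axis=0)
    return np.sqrt(sse / n)


def cv_rmse_path_subsets(
    X: np.ndarray,
    y: np.ndarray,
    subset_masks: np.ndarray,
    max_lv: int,
    folds: list[np.ndarray],
    chunk: int = 256,
) -> np.ndarray:
    """Min-over-LV k-fold RMSECV for many band subsets at once.

    ``subset_masks`` is an (R, p) boolean array; returns length-R RMSECV
    values (each minimized over 1..max_lv components).

    Uses the conjugate-gradient formulation of PLS1: k CGLS iterations on
    the centered normal equations produce the least-squares fit over the
    k-step Krylov subspace, which is exactly the k-latent-variable PLS
    fit.  The search directions stay inside each subset's band support
    (restriction of X'r to the mask commutes through the recurrence), so
    every subset in a chunk shares the same dense centered training
    matrix and the whole sweep runs as a few (n x p) @ (p x chunk) GEMMs
    per iteration — no per-subset matrix copies or deflation.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    masks = np.asarray(subset_masks, dtype=bool)
    R, p = masks.shape
    n = X.shape[0]
    max_lv = int(min(max_lv, p, n - max(len(f) for f in folds) - 1))
    max_lv = max(max_lv, 1)
    tiny = 1e-30

    fold_cache = []
    for test in folds:
        train = np.setdiff1d(np.arange(n), test)
        x_mean = X[train].mean(axis=0)
        y_mean = y[train].mean()
        fold_cache.append(
            (X[train] - x_mean, y[train] - y_mean, X[test] - x_mean, y[test] - y_mean)
        )

    out = np.empty(R)
    for start in range(0, R, chunk):
        Mt = masks[start : start + chunk].T.astype(float)  # p x G
        G = Mt.shape[1]
        sse = np.zeros((G, max_lv))
        for A, ytr, Ate, yte in fold_cache:
            r = np.repeat(ytr[:, None], G, axis=1)  # ntr x G residuals
            s = Mt * (A.T @ r)  # p x G, masked gradient
            p_dir = s.copy()
            gamma = (s * s).sum(axis=0)
            yhat_te = np.zeros((Ate.shape[0], G))
            for k in range(max_lv):
                q = A @ p_dir  # ntr x G
                delta = (q * q).sum(axis=0)
                alpha = np.where(delta > tiny, gamma / np.where(delta > tiny, delta, 1.0), 0.0)
                r -= alpha * q
                yhat_te += alpha * (Ate @ p_dir)
                sse[:, k] += ((yte[:, None] - yhat_te) ** 2).sum(axis=0)
                s = Mt * (A.T @ r)
                gamma_new = (s * s).sum(axis=0)
                beta = np.where(gamma > tiny, gamma_new / np.where(gamma > tiny, gamma, 1.0), 0.0)
                p_dir = s + beta * p_dir
                gamma = gamma_new
        rmse = np.sqrt(sse / n)
        out[start : start + chunk] = rmse.min(axis=1)
    return out
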