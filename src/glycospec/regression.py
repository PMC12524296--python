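"""Calibration models and evaluation: PLSR (NIPALS), RBF-SVR, LOOCV, metrics.

Metrics follow the usual chemometric conventions: R^2 is one minus the
ratio of residual to total sum of squares about the mean of the *actual*
values in the evaluated set; RMSE is in ppm; RPD is the standard
deviation of the prediction-set reference values over RMSEp (>2.5 good,
1.4-1.8 fair).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.svm import SVR

from ._pls import cv_rmse_path, kfold_indices, nipals_pls1, pls1_predict_path
from .preprocess import PreprocessSpec, apply_chain, parse_chain

__all__ = [
    "PredictionSet",
    "EvalMetrics",
    "PLSModel",
    "SVMModel",
    "r_squared",
    "rmse",
    "rpd",
    "pls_fit",
    "pls_predict",
    "select_lv",
    "svr_fit",
    "svr_predict",
    "tune_svr",
    "loocv",
    "split_70_30",
    "evaluate_split",
]


@dataclass
class PredictionSet:
    """Paired actual/predicted TGA values (ppm)."""

    y_true: np.ndarray
    y_pred: np.ndarray

    def __post_init__(self) -> None:
        self.y_true = np.asarray(self.y_true, dtype=float).ravel()
        self.y_pred = np.asarray(self.y_pred, dtype=float).ravel()
        if self.y_true.size != self.y_pred.size:
            raise ValueError("actual and predicted lengths differ")
        if self.y_true.size < 1:
            raise ValueError("empty prediction set")

    @property
    def n(self) -> int:
        return self.y_true.size

    @property
    def mean_actual(self) -> float:
        return float(self.y_true.mean())


def r_squared(pred: PredictionSet) -> float:
    """1 - SS_res / SS_tot, SS_tot about the mean of the actual values."""
    ss_tot = float(((pred.y_true - pred.mean_actual) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("actual values are all equal; R^2 undefined")
    ss_res = float(((pred.y_true - pred.y_pred) ** 2).sum())
    return 1.0 - ss_res / ss_tot


def rmse(pred: PredictionSet) -> float:
    """Root mean squared prediction error (ppm)."""
    return float(np.sqrt(((pred.y_true - pred.y_pred) ** 2).mean()))


def rpd(sd_p: float, rmse_p: float) -> float:
    """Residual predictive deviation: SD of reference values / RMSEp."""
    if rmse_p <= 0:
        raise ValueError("rmse_p must be > 0")
    return sd_p / rmse_p


@dataclass
class EvalMetrics:
    """Cross-validation / calibration / prediction metrics for one model."""

    r2_cv: float | None = None
    rmse_cv: float | None = None
    r2_c: float | None = None
    rmse_c: float | None = None
    r2_p: float | None = None
    rmse_p: float | None = None
    rpd: float | None = None
    sd_p: float | None = None
    n_lv: int | None = None
    C: float | None = None
    epsilon: float | None = None

    def as_row(self) -> dict:
        return {
            "R2cv": self.r2_cv, "RMSEcv": self.rmse_cv,
            "R2c": self.r2_c, "RMSEc": self.rmse_c,
            "R2p": self.r2_p, "RMSEp": self.rmse_p,
            "RPD": self.rpd, "SDp": self.sd_p,
            "LV": self.n_lv, "C": self.C, "epsilon": self.epsilon,
        }


# ---------------------------------------------------------------------------
# PLSR


@dataclass
class PLSModel:
    """Fitted NIPALS PLS1 model (mean-centered X and y)."""

    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray     # p x k
    loadings: np.ndarray    # p x k
    y_loadings: np.ndarray  # k
    scores: np.ndarray      # n x k (training)
    coef: np.ndarray        # collapsed p-vector
    n_lv: int


def pls_fit(X: np.ndarray, y: np.ndarray, n_lv: int) -> PLSModel:
    """Fit PLS1 by NIPALS with ``n_lv`` latent variables."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least 2 samples")
    if not (1 <= n_lv <= min(n - 1, p)):
        raise ValueError(f"n_lv must be in [1, {min(n - 1, p)}], got {n_lv}")
    if np.ptp(y) == 0:
        raise ValueError("response has zero variance")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    W, P, q, T = nipals_pls1(X - x_mean, y - y_mean, n_lv)
    # collapsed coefficients: B = W (P'W)^-1 q
    PtW = P.T @ W
    coef = W @ np.linalg.solve(PtW, q)
    return PLSModel(
        x_mean=x_mean, y_mean=y_mean, weights=W, loadings=P,
        y_loadings=q, scores=T, coef=coef, n_lv=n_lv,
    )


def pls_predict(model: PLSModel, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    return (X - model.x_mean) @ model.coef + model.y_mean


def select_lv(
    X: np.ndarray,
    y: np.ndarray,
    max_lv: int = 15,
    cv_folds: int = 5,
    rng: np.random.Generator | None = None,
) -> int:
    """Latent-variable count minimizing k-fold RMSECV; ties -> fewest LVs."""
    if max_lv < 1:
        raise ValueError("max_lv must be >= 1")
    n = np.asarray(X).shape[0]
    folds = kfold_indices(n, min(cv_folds, n), rng)
    path = cv_rmse_path(X, y, max_lv, folds)
    return int(np.argmin(path)) + 1


# ---------------------------------------------------------------------------
# SVR


@dataclass
class SVMModel:
    """RBF epsilon-SVR with training-statistics input standardization."""

    svr: SVR
    x_mean: np.ndarray
    x_scale: np.ndarray
    C: float
    epsilon: float


def svr_fit(X: np.ndarray, y: np.ndarray, C: float = 100.0, epsilon: float = 5.0) -> SVMModel:
    if C <= 0:
        raise ValueError("C must be > 0")
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    x_mean = X.mean(axis=0)
    x_scale = X.std(axis=0)
    x_scale[x_scale == 0] = 1.0
    svr = SVR(kernel="rbf", C=C, epsilon=epsilon, gamma="scale")
    svr.fit((X - x_mean) / x_scale, y)
    return SVMModel(svr=svr, x_mean=x_mean, x_scale=x_scale, C=C, epsilon=epsilon)


def svr_predict(model: SVMModel, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    return model.svr.predict((X - model.x_mean) / model.x_scale)


def tune_svr(
    X: np.ndarray,
    y: np.ndarray,
    C_grid: Sequence[float] = (1.0, 10.0, 100.0, 1000.0),
    eps_grid: Sequence[float] = (1.0, 5.0, 10.0, 20.0),
    cv_folds: int = 5,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Grid-minimize k-fold RMSECV; ties favour smaller C, then larger eps.

    The winning pair is meant to be frozen for every SVR model in a run.
    """
    if len(C_grid) == 0 or len(eps_grid) == 0:
        raise ValueError("grids must be nonempty")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    folds = kfold_indices(X.shape[0], min(cv_folds, X.shape[0]), rng)
    best = None
    # iteration order implements the tie-break: larger eps first, smaller C first
    for eps in sorted(eps_grid, reverse=True):
        for C in sorted(C_grid):
            sse = 0.0
            for test in folds:
                train = np.setdiff1d(np.arange(X.shape[0]), test)
                model = svr_fit(X[train], y[train], C=C, epsilon=eps)
                resid = y[test] - svr_predict(model, X[test])
                sse += float(resid @ resid)
            score = np.sqrt(sse / X.shape[0])
            if best is None or score < best[0] - 1e-12:
                best = (score, C, eps)
    return best[1], best[2]


# ---------------------------------------------------------------------------
# Evaluation schemes


def loocv(
    fit: Callable[[np.ndarray, np.ndarray], object],
    predict: Callable[[object, np.ndarray], np.ndarray],
    X: np.ndarray,
    y: np.ndarray,
    chain: "PreprocessSpec | str | Sequence" = "none",
    bands: np.ndarray | None = None,
) -> PredictionSet:
    """Leave-one-out CV with per-fold pre-processing refit.

    Response-dependent chain steps are refit on each fold's n-1 training
    rows; the held-out row only ever passes through frozen transforms.
    The chain always sees the full spectrum; ``bands`` restricts the
    model to selected columns *after* pre-processing (derivatives and
    OSC are defined on the full grid).  Returns the pooled out-of-fold
    predictions in sample order.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if n < 3:
        raise ValueError("LOOCV needs at least 3 samples")
    spec = parse_chain(chain)
    sel = slice(None) if bands is None else np.asarray(bands, dtype=int)
    preds = np.empty(n)
    if not spec.uses_response:
        # y-free rowwise steps act identically whether or not fold-split
        Xp = X if not spec.steps else apply_chain(spec, X)[0]
        Xp = Xp[:, sel]
        for i in range(n):
            train = np.delete(np.arange(n), i)
            model = fit(Xp[train], y[train])
            preds[i] = predict(model, Xp[i : i + 1])[0]
    else:
        for i in range(n):
            train = np.delete(np.arange(n), i)
            Xtr, Xte = apply_chain(spec, X[train], y[train], X[i : i + 1])
            model = fit(Xtr[:, sel], y[train])
            preds[i] = predict(model, Xte[:, sel])[0]
    return PredictionSet(y_true=y, y_pred=preds)


def split_70_30(
    n: int, seed: int, stratify: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Random 70:30 train/test index split; train size = round(0.7 n).

    Optionally stratified on a label array (split applied per level).
    """
    if n < 10:
        raise ValueError("split needs at least 10 samples")
    rng = np.random.default_rng(seed)
    if stratify is None:
        order = rng.permutation(n)
        n_train = round(0.7 * n)
        return np.sort(order[:n_train]), np.sort(order[n_train:])
    train_parts, test_parts = [], []
    for level in np.unique(stratify):
        idx = np.flatnonzero(stratify == level)
        order = rng.permutation(idx.size)
        n_train = round(0.7 * idx.size)
        train_parts.append(idx[order[:n_train]])
        test_parts.append(idx[order[n_train:]])
    return np.sort(np.concatenate(train_parts)), np.sort(np.concatenate(test_parts))


def evaluate_split(
    fit: Callable[[np.ndarray, np.ndarray], object],
    predict: Callable[[object, np.ndarray], np.ndarray],
    X: np.ndarray,
    y: np.ndarray,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    chain: "PreprocessSpec | str | Sequence" = "none",
    bands: np.ndarray | None = None,
) -> tuple[EvalMetrics, PredictionSet, PredictionSet]:
    """Calibration (train) and prediction (test) metrics for one split."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    sel = slice(None) if bands is None else np.asarray(bands, dtype=int)
    Xtr, Xte = apply_chain(chain, X[train_idx], y[train_idx], X[test_idx])
    Xtr, Xte = Xtr[:, sel], Xte[:, sel]
    model = fit(Xtr, y[train_idx])
    cal = PredictionSet(y[train_idx], predict(model, Xtr))
    pred = PredictionSet(y[test_idx], predict(model, Xte))
    sd_p = float(np.std(pred.y_true, ddof=1))
    metrics = EvalMetrics(
        r2_c=r_squared(cal), rmse_c=rmse(cal),
        r2_p=r_squared(pred), rmse_p=rmse(pred),
        sd_p=sd_p, rpd=rpd(sd_p, rmse(pred)),
    )
    return metrics, cal, pred
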