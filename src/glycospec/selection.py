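"""Wavelength selection: CARS, IRIV and greedy backward elimination.

All three selectors score candidate band subsets with the same evaluator:
5-fold cross-validated RMSE of a NIPALS PLS1 model, minimized over the
latent-variable path (folds fixed per call by the seed).  CARS couples an
exponentially decaying retention schedule (EDF) with |beta|-weighted
resampling (ARS); IRIV classifies each band by a paired Mann-Whitney
comparison of RMSECV with the band included versus flipped out across
random binary subsets (BMSF-style), dropping uninformative and
interfering bands each round; backward elimination removes one band at a
time while performance does not degrade beyond a tolerance.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy import stats as _sstats

from ._pls import cv_rmse_path, cv_rmse_path_subsets, kfold_indices, nipals_pls1

__all__ = [
    "SelectionResult",
    "mann_whitney_u",
    "cars",
    "backward_eliminate",
    "iriv",
]


@dataclass
class SelectionResult:
    """Outcome of one selector run, with enough trace to re-plot it."""

    method: str
    selected: np.ndarray
    trace: dict = field(default_factory=dict)
    seed: int | None = None
    settings: dict = field(default_factory=dict)
    wavelengths_nm: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.selected = np.sort(np.asarray(self.selected, dtype=int))
        if self.selected.size == 0:
            raise ValueError("selection must be nonempty")

    @property
    def selected_nm(self) -> np.ndarray | None:
        if self.wavelengths_nm is None:
            return None
        return self.wavelengths_nm[self.selected]

    def to_json(self, path: str | Path) -> None:
        def _clean(obj):
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, (np.integer,)):
                return int(obj)
            if isinstance(obj, (np.floating,)):
                return float(obj)
            if isinstance(obj, dict):
                return {k: _clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [_clean(v) for v in obj]
            return obj

        payload = {
            "method": self.method,
            "selected": self.selected.tolist(),
            "selected_nm": None if self.selected_nm is None else self.selected_nm.tolist(),
            "trace": _clean(self.trace),
            "seed": self.seed,
            "settings": _clean(self.settings),
        }
        Path(path).write_text(json.dumps(payload, indent=2))


# ---------------------------------------------------------------------------
# Mann-Whitney U


def mann_whitney_u(sample_a: Sequence[float], sample_b: Sequence[float]) -> tuple[float, float]:
    """U statistic (for sample_a, midrank ties) and two-sided p.

    Exact p by enumeration of all group labelings when m + n <= 12;
    otherwise the normal approximation with tie correction and a 0.5
    continuity correction.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    m, n = a.size, b.size
    if m == 0 or n == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    ranks = _sstats.rankdata(pooled)
    u_a = float(ranks[:m].sum() - m * (m + 1) / 2.0)

    if m + n <= 12:
        u_obs = min(u_a, m * n - u_a)
        count = 0
        total = 0
        for combo in itertools.combinations(range(m + n), m):
            r = ranks[list(combo)].sum()
            u = r - m * (m + 1) / 2.0
            u = min(u, m * n - u)
            total += 1
            if u <= u_obs + 1e-9:
                count += 1
        p = min(1.0, count / total)
        return u_a, p

    mu = m * n / 2.0
    N = m + n
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum()) / (N * (N - 1))
    sigma2 = m * n / 12.0 * ((N + 1) - tie_term)
    if sigma2 <= 0:
        return u_a, 1.0
    diff = u_a - mu
    cc = 0.5 * np.sign(diff)
    z = (diff - cc) / np.sqrt(sigma2)
    p = min(1.0, 2.0 * float(_sstats.norm.sf(abs(z))))
    return u_a, p


# ---------------------------------------------------------------------------
# Shared evaluator


def _rmsecv(X: np.ndarray, y: np.ndarray, bands: np.ndarray, max_lv: int, folds) -> float:
    """Min-over-LV k-fold RMSECV of a PLS1 model on the given bands."""
    return float(cv_rmse_path(X[:, bands], y, max_lv, folds).min())


# ---------------------------------------------------------------------------
# CARS


def cars(
    X: np.ndarray,
    y: np.ndarray,
    n_runs: int = 50,
    mc_sample_ratio: float = 0.8,
    cv_folds: int = 5,
    max_lv: int = 15,
    seed: int | None = None,
    wavelengths_nm: np.ndarray | None = None,
) -> SelectionResult:
    """Competitive adaptive reweighted sampling.

    Per run: draw a Monte-Carlo sample subset, fit PLS on the currently
    retained bands, weight bands by normalized |beta|, shrink the
    retention budget along the EDF (all p bands at run 1 down to 2 at run
    ``n_runs``), resample retained bands proportionally to weight, and
    record the retained set's full-sample RMSECV.  Returns the retained
    set of the run with minimal RMSECV.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if p < 3:
        raise ValueError("need at least 3 bands")
    if n < cv_folds:
        raise ValueError("need at least cv_folds samples")
    rng = np.random.default_rng(seed)
    folds = kfold_indices(n, cv_folds, rng)

    # EDF pinned at r_1 = 1 (all p) and r_N = 2/p (two bands)
    a = (p / 2.0) ** (1.0 / (n_runs - 1))
    k = np.log(p / 2.0) / (n_runs - 1)
    runs = np.arange(1, n_runs + 1)
    ratios = a * np.exp(-k * runs)
    budgets = np.minimum(np.ceil(ratios * p).astype(int), p)
    budgets = np.maximum(budgets, 2)

    n_mc = int(np.ceil(mc_sample_ratio * n))
    retained = np.arange(p)
    trace_counts, trace_rmsecv, trace_coefs, trace_sets = [], [], [], []

    for i in range(n_runs):
        mc = rng.choice(n, size=n_mc, replace=False)
        Xs = X[np.ix_(mc, retained)]
        ys = y[mc]
        n_lv = int(min(max_lv, retained.size, n_mc - 1))
        x_mean = Xs.mean(axis=0)
        y_mean = ys.mean()
        W, P, q, _ = nipals_pls1(Xs - x_mean, ys - y_mean, n_lv)
        PtW = P.T @ W
        # guard rank-deficient tail components
        diag = np.abs(np.diag(PtW))
        keep = diag > 1e-12
        if not np.all(keep):
            kk = int(np.flatnonzero(~keep)[0]) if (~keep).any() else n_lv
            kk = max(kk, 1)
            W, P, q = W[:, :kk], P[:, :kk], q[:kk]
            PtW = P.T @ W
        beta = np.abs(W @ np.linalg.solve(PtW, q))
        weights = beta / beta.sum() if beta.sum() > 0 else np.full(retained.size, 1.0 / retained.size)

        budget = int(budgets[i])
        positive = weights > 0
        n_take = int(min(budget, positive.sum(), retained.size))
        if n_take < 2:
            raise RuntimeError("CARS retention budget collapsed below 2 bands")
        probs = weights[positive] / weights[positive].sum()
        pick = rng.choice(np.flatnonzero(positive), size=n_take, replace=False, p=probs)
        coefs_full = np.zeros(p)
        coefs_full[retained] = beta
        retained = np.sort(retained[pick])

        score = _rmsecv(X, y, retained, max_lv, folds)
        trace_counts.append(retained.size)
        trace_rmsecv.append(score)
        trace_coefs.append(coefs_full)
        trace_sets.append(retained.copy())

    best = int(np.argmin(trace_rmsecv))
    return SelectionResult(
        method="cars",
        selected=trace_sets[best],
        trace={
            "retained_counts": np.array(trace_counts),
            "rmsecv": np.array(trace_rmsecv),
            "coef_magnitudes": np.array(trace_coefs),
            "best_run": best,
            "edf_ratios": ratios,
        },
        seed=seed,
        settings={
            "n_runs": n_runs, "mc_sample_ratio": mc_sample_ratio,
            "cv_folds": cv_folds, "max_lv": max_lv,
        },
        wavelengths_nm=None if wavelengths_nm is None else np.asarray(wavelengths_nm),
    )


# ---------------------------------------------------------------------------
# Backward elimination


def backward_eliminate(
    X: np.ndarray,
    y: np.ndarray,
    initial_bands: Sequence[int],
    tolerance: float = 0.0,
    cv_folds: int = 5,
    max_lv: int = 15,
    seed: int | None = None,
    wavelengths_nm: np.ndarray | None = None,
) -> SelectionResult:
    """Greedy one-at-a-time removal of the least useful band.

    At each step the band whose removal yields the lowest evaluator
    RMSECV goes; the removal is accepted only while RMSECV does not
    worsen by more than ``tolerance`` (ties removed lowest index first).
    Stops otherwise, or at one band.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    current = np.sort(np.asarray(initial_bands, dtype=int))
    if current.size < 2:
        raise ValueError("initial set must have at least 2 bands")
    rng = np.random.default_rng(seed)
    folds = kfold_indices(X.shape[0], cv_folds, rng)
    p = X.shape[1]

    base = _rmsecv(X, y, current, max_lv, folds)
    trace_rmsecv = [base]
    trace_removed: list[int] = []

    while current.size > 1:
        masks = np.zeros((current.size, p), dtype=bool)
        masks[:, current] = True
        for row, band in enumerate(current):
            masks[row, band] = False
        scores = cv_rmse_path_subsets(X, y, masks, max_lv, folds)
        j = int(np.argmin(scores))  # first occurrence = lowest band index
        if scores[j] > base + tolerance:
            break
        base = float(scores[j])
        trace_removed.append(int(current[j]))
        trace_rmsecv.append(base)
        current = np.delete(current, j)

    return SelectionResult(
        method="backward_elimination",
        selected=current,
        trace={
            "rmsecv": np.array(trace_rmsecv),
            "removed": np.array(trace_removed, dtype=int),
        },
        seed=seed,
        settings={"tolerance": tolerance, "cv_folds": cv_folds, "max_lv": max_lv},
        wavelengths_nm=None if wavelengths_nm is None else np.asarray(wavelengths_nm),
    )


# ---------------------------------------------------------------------------
# IRIV


def iriv(
    X: np.ndarray,
    y: np.ndarray,
    n_rows: int = 500,
    inclusion_prob: float = 0.5,
    alpha: float = 0.05,
    max_rounds: int = 10,
    cv_folds: int = 5,
    max_lv: int = 15,
    seed: int | None = None,
    wavelengths_nm: np.ndarray | None = None,
) -> SelectionResult:
    """Iteratively retaining informative variables (BMSF-style).

    Each round draws a random binary inclusion matrix over the surviving
    bands, scores every row's subset by RMSECV, and for each band pairs
    the rows that include it against the same rows with the band flipped
    out.  A Mann-Whitney test on the two RMSECV samples classifies the
    band: strongly/weakly informative when exclusion worsens RMSECV
    (p below / above alpha), uninformative/interfering otherwise.
    Uninformative and interfering bands are dropped; rounds repeat until
    nothing is dropped or ``max_rounds``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if p < 3:
        raise ValueError("need at least 3 bands")
    rng = np.random.default_rng(seed)
    folds = kfold_indices(n, cv_folds, rng)

    current = np.arange(p)
    rounds_trace = []

    for round_no in range(1, max_rounds + 1):
        pc = current.size
        if pc < 3:
            break
        M = rng.random((n_rows, pc)) < inclusion_prob
        # every row needs >= 2 bands so a flip never empties it
        for r in np.flatnonzero(M.sum(axis=1) < 2):
            M[r, rng.choice(pc, size=2, replace=False)] = True

        full_masks = np.zeros((n_rows, p), dtype=bool)
        full_masks[:, current] = M
        base_scores = cv_rmse_path_subsets(X, y, full_masks, max_lv, folds)

        # flipped counterparts, only for (row, band) cells with the band in
        flip_rows, flip_bands = np.nonzero(M)
        flip_masks = full_masks[flip_rows].copy()
        flip_masks[np.arange(flip_rows.size), current[flip_bands]] = False
        flip_scores = cv_rmse_path_subsets(X, y, flip_masks, max_lv, folds)

        classes = np.empty(pc, dtype=object)
        stats_rows = []
        drop_local = []
        for j in range(pc):
            sel = flip_bands == j
            a_scores = base_scores[flip_rows[sel]]   # band included
            b_scores = flip_scores[sel]              # band flipped out
            if a_scores.size == 0:
                classes[j] = "uninformative"
                drop_local.append(j)
                continue
            u, pval = mann_whitney_u(a_scores, b_scores)
            worsens = b_scores.mean() > a_scores.mean()
            if worsens and pval < alpha:
                cls = "strongly informative"
            elif worsens:
                cls = "weakly informative"
            elif pval < alpha:
                cls = "interfering"
            else:
                cls = "uninformative"
            classes[j] = cls
            stats_rows.append(
                {
                    "band": int(current[j]),
                    "mean_included": float(a_scores.mean()),
                    "mean_excluded": float(b_scores.mean()),
                    "U": u,
                    "p": pval,
                    "class": cls,
                }
            )
            if cls in ("uninformative", "interfering"):
                drop_local.append(j)

        rounds_trace.append({"round": round_no, "n_bands": pc, "table": stats_rows})
        if len(drop_local) == pc:
            raise RuntimeError(
                f"IRIV dropped every band in round {round_no}; no informative signal"
            )
        if not drop_local:
            break
        current = np.delete(current, drop_local)

    return SelectionResult(
        method="iriv",
        selected=current,
        trace={"rounds": rounds_trace},
        seed=seed,
        settings={
            "n_rows": n_rows, "inclusion_prob": inclusion_prob, "alpha": alpha,
            "max_rounds": max_rounds, "cv_folds": cv_folds, "max_lv": max_lv,
        },
        wavelengths_nm=None if wavelengths_nm is None else np.asarray(wavelengths_nm),
    )
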