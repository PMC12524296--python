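"""Spectral pre-processing: SNV, Savitzky-Golay derivatives, OSC, chains.

Chains are ordered left-to-right as named in calibration-transfer
shorthand: ``"snv + 1st derivative"`` applies SNV first, then the
derivative.  Row-wise steps (SNV, derivative, absolute value) have no
fitted state and act identically on every spectrum; orthogonal signal
correction (OSC) is response-dependent and is always fit on training
rows only, then applied frozen to test rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import savgol_filter

__all__ = [
    "ChainError",
    "DegenerateSpectrumError",
    "snv",
    "sg_derivative",
    "OSC",
    "Step",
    "PreprocessSpec",
    "apply_chain",
    "parse_chain",
    "CHAIN_ALIASES",
]


class ChainError(ValueError):
    """Invalid pre-processing chain specification."""


class DegenerateSpectrumError(ValueError):
    """A spectrum with no spread cannot be SNV-scaled."""


def snv(X: np.ndarray) -> np.ndarray:
    """Standard normal variate: center each row to mean 0, scale to sample sd 1.

    Removes multiplicative scatter and additive offsets per spectrum.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    if np.any(sd == 0):
        bad = int(np.argmax(sd == 0))
        raise DegenerateSpectrumError(f"row {bad} is constant; SNV undefined")
    return (X - mean) / sd


def sg_derivative(
    X: np.ndarray, window: int = 11, polyorder: int = 2, order: int = 1
) -> np.ndarray:
    """Savitzky-Golay derivative along the spectral axis, per band index.

    The grid is uniform, so a per-index derivative is proportional to a
    per-nm derivative; edge values come from the polynomial fitted to the
    terminal windows.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if window % 2 == 0 or window <= polyorder:
        raise ChainError(
            f"window must be odd and > polyorder (got window={window}, "
            f"polyorder={polyorder})"
        )
    if order > polyorder:
        raise ChainError("derivative order cannot exceed polyorder")
    if X.shape[1] < window:
        raise ChainError(
            f"need at least window={window} bands, got {X.shape[1]}"
        )
    return savgol_filter(X, window, polyorder, deriv=order, delta=1.0, axis=1, mode="interp")


class OSC:
    """Orthogonal signal correction (NIPALS-style orthogonalized deflation).

    Removes ``n_components`` score/loading pairs from X whose scores are
    exactly orthogonal to the training response, i.e. structured variance
    (scatter, baseline) that cannot help predict y.  Each component's
    score is constrained to the column space of X so that it can be
    reproduced on unseen rows as ``t = (X_new - x_mean) @ w``; training
    deflation and `transform` on the training matrix agree exactly.
    """

    def __init__(self, n_components: int = 1, max_iter: int = 200, tol: float = 1e-12):
        if n_components < 1:
            raise ChainError("n_components must be >= 1")
        self.n_components = n_components
        self.max_iter = max_iter
        self.tol = tol
        self.weights_: np.ndarray | None = None  # p x k
        self.loadings_: np.ndarray | None = None  # p x k
        self.x_mean_: np.ndarray | None = None
        self.training_scores_: np.ndarray | None = None  # n x k
        self.training_y_: np.ndarray | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "OSC":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.shape[0] != y.size:
            raise ValueError("X rows must match y length")
        if self.n_components >= min(X.shape):
            raise ChainError(
                f"n_components={self.n_components} must be < rank bound "
                f"min(n, p)={min(X.shape)}"
            )
        self.x_mean_ = X.mean(axis=0)
        Xd = X - self.x_mean_
        yc = y - y.mean()
        y_norm2 = float(yc @ yc)
        if y_norm2 == 0:
            raise ValueError("response has zero variance; OSC undefined")

        W, P, T = [], [], []
        for _ in range(self.n_components):
            # initialize with the dominant direction of the y-orthogonal part
            Z = Xd - np.outer(yc, (yc @ Xd) / y_norm2)
            u, s, vt = np.linalg.svd(Z, full_matrices=False)
            t = u[:, 0] * s[0]
            # alternate projections onto col(Xd) and the y-orthogonal complement
            for _ in range(self.max_iter):
                w, *_ = np.linalg.lstsq(Xd, t, rcond=None)
                t_new = Xd @ w
                t_new = t_new - yc * (yc @ t_new) / y_norm2
                w, *_ = np.linalg.lstsq(Xd, t_new, rcond=None)
                t_fit = Xd @ w
                delta = np.linalg.norm(t_fit - t) / max(np.linalg.norm(t_fit), 1e-30)
                t = t_fit
                if delta < self.tol:
                    break
            tt = float(t @ t)
            if tt <= 0:
                raise ChainError("OSC component degenerated to zero variance")
            p_load = Xd.T @ t / tt
            Xd = Xd - np.outer(t, p_load)
            W.append(w)
            P.append(p_load)
            T.append(t)

        self.weights_ = np.column_stack(W)
        self.loadings_ = np.column_stack(P)
        self.training_scores_ = np.column_stack(T)
        self.training_y_ = y.copy()
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.weights_ is None:
            raise RuntimeError("OSC must be fit before transform")
        X = np.asarray(X, dtype=float)
        Xd = X - self.x_mean_
        for k in range(self.n_components):
            t = Xd @ self.weights_[:, k]
            Xd = Xd - np.outer(t, self.loadings_[:, k])
        # restore the training mean so the output stays on the reflectance scale
        return Xd + self.x_mean_

    def fit_transform(self, X: np.ndarray, y: np.ndarray) -> np.ndarray:
        return self.fit(X, y).transform(X)


# ---------------------------------------------------------------------------
# Chain specification


@dataclass(frozen=True)
class Step:
    """One named chain step with its parameters."""

    name: str  # none | snv | sg_derivative | abs | osc
    params: tuple = ()

    def __str__(self) -> str:
        if not self.params:
            return self.name
        return f"{self.name}({', '.join(map(str, self.params))})"


def step_snv() -> Step:
    return Step("snv")


def step_derivative(window: int = 11, polyorder: int = 2, order: int = 1) -> Step:
    return Step("sg_derivative", (window, polyorder, order))


def step_abs() -> Step:
    return Step("abs")


def step_osc(n_components: int = 1) -> Step:
    return Step("osc", (n_components,))


@dataclass
class PreprocessSpec:
    """Ordered pre-processing chain with validation.

    Constraints: at most one OSC step; `abs` only immediately after a
    derivative; derivative windows odd and larger than the polyorder.
    """

    steps: tuple[Step, ...] = ()
    name: str = ""

    def __post_init__(self) -> None:
        steps = tuple(s for s in self.steps if s.name != "none")
        self.steps = steps
        n_osc = sum(1 for s in steps if s.name == "osc")
        if n_osc > 1:
            raise ChainError("osc may appear at most once in a chain")
        for i, s in enumerate(steps):
            if s.name not in {"snv", "sg_derivative", "abs", "osc"}:
                raise ChainError(f"unknown step '{s.name}'")
            if s.name == "abs":
                if i == 0 or steps[i - 1].name != "sg_derivative":
                    raise ChainError("abs is only valid immediately after a derivative")
            if s.name == "sg_derivative":
                window, polyorder, _ = s.params
                if window % 2 == 0 or window <= polyorder:
                    raise ChainError(
                        f"derivative window must be odd and > polyorder "
                        f"(got {window}, {polyorder})"
                    )
        if not self.name:
            self.name = " + ".join(str(s) for s in steps) if steps else "none"

    @property
    def uses_response(self) -> bool:
        return any(s.name == "osc" for s in self.steps)

    def to_config(self) -> list:
        return [{"name": s.name, "params": list(s.params)} for s in self.steps]


#: row labels used in the study's report tables -> chains
CHAIN_ALIASES: dict[str, tuple[Step, ...]] = {
    "none": (),
    "1st derivative": (step_derivative(),),
    "snv + 1st derivative": (step_snv(), step_derivative()),
    "osc + 1st derivative": (step_osc(), step_derivative()),
    "|1st der| + snv": (step_derivative(), step_abs(), step_snv()),
}


def parse_chain(spec: "PreprocessSpec | str | Sequence") -> PreprocessSpec:
    """Accept a PreprocessSpec, a table row label, or a list of step dicts."""
    if isinstance(spec, PreprocessSpec):
        return spec
    if isinstance(spec, str):
        key = spec.strip().lower()
        if key not in CHAIN_ALIASES:
            raise ChainError(
                f"unknown chain '{spec}'; known: {sorted(CHAIN_ALIASES)}"
            )
        return PreprocessSpec(steps=CHAIN_ALIASES[key], name=key)
    steps = []
    for item in spec:
        if isinstance(item, Step):
            steps.append(item)
        else:
            steps.append(Step(item["name"], tuple(item.get("params", ()))))
    return PreprocessSpec(steps=tuple(steps))


def apply_chain(
    spec: "PreprocessSpec | str | Sequence",
    X_train: np.ndarray,
    y_train: np.ndarray | None = None,
    X_test: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Apply a chain left-to-right; returns (X_train', X_test').

    Response-dependent steps (OSC) are fit on the training rows only and
    applied frozen to the test rows; the test response is never seen.
    """
    spec = parse_chain(spec)
    Xtr = np.array(X_train, dtype=float)
    Xte = None if X_test is None else np.array(X_test, dtype=float)
    for s in spec.steps:
        if s.name == "snv":
            Xtr = snv(Xtr)
            Xte = None if Xte is None else snv(Xte)
        elif s.name == "sg_derivative":
            Xtr = sg_derivative(Xtr, *s.params)
            Xte = None if Xte is None else sg_derivative(Xte, *s.params)
        elif s.name == "abs":
            Xtr = np.abs(Xtr)
            Xte = None if Xte is None else np.abs(Xte)
        elif s.name == "osc":
            if y_train is None:
                raise ChainError("osc requires the training response")
            osc = OSC(n_components=s.params[0])
            Xtr = osc.fit_transform(Xtr, np.asarray(y_train))
            Xte = None if Xte is None else osc.transform(Xte)
    return Xtr, Xte
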