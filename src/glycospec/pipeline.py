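"""Experiment orchestration: pre-processing x selector x regressor grids.

One `RunConfig` describes a whole experiment; `run_experiment` executes
every combination deterministically under a single global seed and emits
a report table mirroring the usual chemometric layout (model,
pre-processing, R2cv, RMSEcv, R2c, RMSEc, R2p, RMSEp, RPD) plus the
selected wavelength lists.  Per-stage seeds are fanned out from the
global seed via ``SeedSequence((global_seed, crc32(stage_name)))`` so
any stage can be reproduced in isolation.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import regression as reg
from .hypercube import SpectralDataset
from .preprocess import CHAIN_ALIASES, parse_chain
from .selection import SelectionResult, backward_eliminate, cars, iriv
from .synthetic import SyntheticConfig, generate_dataset

__all__ = [
    "RunConfig",
    "ReportTable",
    "stage_seed",
    "run_experiment",
    "load_fixture",
    "nearest_band_indices",
    "report",
]

logger = logging.getLogger("glycospec")

REPORT_COLUMNS = [
    "selector", "preprocessing", "model", "n_selected", "LV", "C", "epsilon",
    "R2cv", "RMSEcv", "R2c", "RMSEc", "R2p", "RMSEp", "RPD", "SDp", "selected_nm",
]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage child seed (< 2^31)."""
    ss = np.random.SeedSequence((int(global_seed), zlib.crc32(stage.encode())))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Everything one experiment needs; serializable to/from YAML."""

    seed: int = 0
    data: SyntheticConfig | str | None = None  # config, dataset CSV path, or None
    chains: tuple[str, ...] = ("none", "1st derivative")
    selectors: tuple[str, ...] = ("full", "cars+be")
    regressors: tuple[str, ...] = ("plsr",)
    loocv: bool = True
    split: bool = False
    stratify_split: bool = False
    output_dir: str | None = None
    max_lv: int = 15
    cv_folds: int = 5
    cars_runs: int = 50
    iriv_rows: int = 500
    iriv_max_lv: int | None = None
    svr_C_grid: tuple[float, ...] = (1.0, 10.0, 100.0, 1000.0)
    svr_eps_grid: tuple[float, ...] = (1.0, 5.0, 10.0, 20.0)

    def __post_init__(self) -> None:
        if not self.chains or not self.selectors or not self.regressors:
            raise ValueError("need at least one chain, selector and regressor")
        for c in self.chains:
            parse_chain(c)
        for s in self.selectors:
            if s not in {"full", "cars+be", "iriv+be"}:
                raise ValueError(f"unknown selector '{s}'")
        for r in self.regressors:
            if r not in {"plsr", "svmr"}:
                raise ValueError(f"unknown regressor '{r}'")

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            k: (v.to_dict() if isinstance(v, SyntheticConfig) else
                list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


@dataclass
class ReportTable:
    """Rows of evaluated combinations plus their selections."""

    frame: pd.DataFrame
    selections: dict[str, SelectionResult] = field(default_factory=dict)

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False, float_format="%.6g")

    @staticmethod
    def read_csv(path: str | Path) -> pd.DataFrame:
        return pd.read_csv(path)

    def to_markdown(self, path: str | Path) -> None:
        show = self.frame.drop(columns=["selected_nm"])
        Path(path).write_text(show.to_markdown(index=False, floatfmt=".3f") + "\n")


def _load_data(config: RunConfig) -> SpectralDataset:
    if config.data is None:
        dataset, _ = generate_dataset(SyntheticConfig(seed=stage_seed(config.seed, "simulate")))
        return dataset
    if isinstance(config.data, SyntheticConfig):
        dataset, _ = generate_dataset(config.data)
        return dataset
    return SpectralDataset.from_csv(config.data)


def _select(
    selector: str,
    Xp: np.ndarray,
    y: np.ndarray,
    wavelengths: np.ndarray,
    config: RunConfig,
) -> tuple[np.ndarray, dict[str, SelectionResult]]:
    results: dict[str, SelectionResult] = {}
    if selector == "full":
        return np.arange(Xp.shape[1]), results
    if selector == "cars+be":
        first = cars(
            Xp, y, n_runs=config.cars_runs, cv_folds=config.cv_folds,
            max_lv=config.max_lv, seed=stage_seed(config.seed, "cars"),
            wavelengths_nm=wavelengths,
        )
        results["cars"] = first
    else:  # iriv+be
        first = iriv(
            Xp, y, n_rows=config.iriv_rows, cv_folds=config.cv_folds,
            max_lv=config.iriv_max_lv or config.max_lv,
            seed=stage_seed(config.seed, "iriv"),
            wavelengths_nm=wavelengths,
        )
        results["iriv"] = first
    if first.selected.size >= 2:
        be = backward_eliminate(
            Xp, y, first.selected, cv_folds=config.cv_folds,
            max_lv=config.max_lv, seed=stage_seed(config.seed, "be"),
            wavelengths_nm=wavelengths,
        )
        results["be"] = be
        return be.selected, results
    return first.selected, results


def run_experiment(config: RunConfig) -> ReportTable:
    """Execute the full grid; deterministic given the config seed.

    Pre-processing for the *selection* stage is fit on the full dataset
    (selection is a modeling choice, not a reported metric); all reported
    cross-validation and split metrics refit response-dependent steps on
    training rows only.
    """
    dataset = _load_data(config)
    X, y, wavelengths = dataset.X, dataset.y, dataset.wavelengths_nm
    rows = []
    selections: dict[str, SelectionResult] = {}

    for chain_name in config.chains:
        chain = parse_chain(chain_name)
        from .preprocess import apply_chain

        Xp, _ = apply_chain(chain, X, y)
        for selector in config.selectors:
            try:
                bands, sel_results = _select(selector, Xp, y, wavelengths, config)
            except Exception:
                logger.exception("selection failed: %s / %s", selector, chain_name)
                continue
            for key, res in sel_results.items():
                selections[f"{selector}|{chain_name}|{key}"] = res
            for regressor in config.regressors:
                try:
                    row = _evaluate_combination(
                        config, X, y, dataset, chain, bands, selector, regressor,
                        wavelengths,
                    )
                except Exception:
                    logger.exception(
                        "evaluation failed: %s / %s / %s", selector, chain_name, regressor
                    )
                    continue
                rows.append(row)
                logger.info(
                    "done selector=%s chain=%s model=%s R2cv=%s",
                    selector, chain_name, regressor, row.get("R2cv"),
                )

    frame = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    table = ReportTable(frame=frame, selections=selections)
    if config.output_dir:
        report(table, config.output_dir, config)
    return table


def _evaluate_combination(
    config: RunConfig,
    X: np.ndarray,
    y: np.ndarray,
    dataset: SpectralDataset,
    chain,
    bands: np.ndarray,
    selector: str,
    regressor: str,
    wavelengths: np.ndarray,
) -> dict:
    from .preprocess import apply_chain

    Xp, _ = apply_chain(chain, X, y)
    Xsel = Xp[:, bands]
    lv_rng = np.random.default_rng(stage_seed(config.seed, "lv-select"))

    metrics = reg.EvalMetrics()
    if regressor == "plsr":
        n_lv = reg.select_lv(Xsel, y, max_lv=config.max_lv,
                             cv_folds=config.cv_folds, rng=lv_rng)
        metrics.n_lv = n_lv

        def fit(A, b, _n_lv=n_lv):
            return reg.pls_fit(A, b, min(_n_lv, A.shape[0] - 1, A.shape[1]))

        predict = reg.pls_predict
    else:
        C, eps = reg.tune_svr(
            Xsel, y, config.svr_C_grid, config.svr_eps_grid,
            cv_folds=config.cv_folds,
            rng=np.random.default_rng(stage_seed(config.seed, "svr-tune")),
        )
        metrics.C, metrics.epsilon = C, eps

        def fit(A, b, _C=C, _eps=eps):
            return reg.svr_fit(A, b, C=_C, epsilon=_eps)

        predict = reg.svr_predict

    if config.loocv:
        pred_cv = reg.loocv(fit, predict, X, y, chain=chain, bands=bands)
        metrics.r2_cv = reg.r_squared(pred_cv)
        metrics.rmse_cv = reg.rmse(pred_cv)
    if config.split:
        train_idx, test_idx = reg.split_70_30(
            X.shape[0], stage_seed(config.seed, "split"),
            stratify=dataset.day if config.stratify_split else None,
        )
        split_metrics, _, _ = reg.evaluate_split(
            fit, predict, X, y, train_idx, test_idx, chain=chain, bands=bands
        )
        metrics.r2_c = split_metrics.r2_c
        metrics.rmse_c = split_metrics.rmse_c
        metrics.r2_p = split_metrics.r2_p
        metrics.rmse_p = split_metrics.rmse_p
        metrics.sd_p = split_metrics.sd_p
        metrics.rpd = split_metrics.rpd

    row = {
        "selector": selector,
        "preprocessing": chain.name,
        "model": regressor,
        "n_selected": int(len(bands)),
        "selected_nm": " ".join(f"{wavelengths[b]:.1f}" for b in bands),
    }
    row.update({k: v for k, v in metrics.as_row().items() if k in REPORT_COLUMNS})
    return row


def report(table: ReportTable, out_dir: str | Path, config: RunConfig | None = None) -> dict:
    """Write report CSV + markdown + selection JSONs; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"csv": out / "report.csv", "md": out / "report.md"}
    table.to_csv(paths["csv"])
    table.to_markdown(paths["md"])
    for key, sel in table.selections.items():
        safe = key.replace("|", "_").replace(" ", "-").replace("/", "-")
        path = out / f"selection_{safe}.json"
        sel.to_json(path)
        paths[key] = path
    if config is not None:
        config.to_yaml(out / "config.yaml")
        paths["config"] = out / "config.yaml"
    return paths


# ---------------------------------------------------------------------------
# Printed selected-wavelength fixtures


def _fixture_tables() -> dict:
    out = {}
    for name in ("table2", "table3"):
        text = resources.files("glycospec.fixtures").joinpath(f"{name}_selections.json").read_text()
        out[name] = json.loads(text)
    return out


def load_fixture(table: str, method: str, preprocessing: str) -> list[float]:
    """Verbatim printed wavelength list (nm) for a (table, method, chain) key."""
    tables = _fixture_tables()
    table = table.lower()
    if table not in tables:
        raise KeyError(f"unknown table '{table}'; available: {sorted(tables)}")
    methods = tables[table]
    method = method.upper()
    if method not in methods:
        raise KeyError(f"unknown method '{method}'; available: {sorted(methods)}")
    chains = methods[method]
    key = preprocessing.strip().lower()
    if key not in chains:
        raise KeyError(
            f"unknown pre-processing '{preprocessing}'; available: {sorted(chains)}"
        )
    return list(chains[key])


def nearest_band_indices(nm_values: Sequence[float], grid_nm: np.ndarray) -> np.ndarray:
    """Map printed wavelengths to nearest grid bands (printed lists do not
    sit exactly on the uniform acquisition grid)."""
    grid = np.asarray(grid_nm, dtype=float)
    return np.array([int(np.argmin(np.abs(grid - v))) for v in nm_values])
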