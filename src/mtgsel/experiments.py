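"""Repeated-split experiment harness: method comparison and ensemble-size sweep.

Each repeat draws a fresh stratified train/test split (seed = base_seed + r);
all methods inside a repeat share that split, so comparisons are paired.  Mean
and standard deviation of test accuracy — and, when a planted truth is
available, of the selection/recovery counts — are reported per method.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .baselines import cv_fit_penalized, filter_then_classify
from .io_data import ExpressionDataset, SplitSpec, split_train_test
from .model_selection import fit_pipeline
from .optimizer import OptimizerOptions
from .simulate import selection_metrics

__all__ = ["ExperimentConfig", "run_comparison", "sweep_num_tasks", "METHODS"]

METHODS = ("ours", "l1", "elastic_net", "mrmr", "relieff")


@dataclass
class ExperimentConfig:
    """Knobs of the comparison protocol."""

    train_fractions: tuple[float, ...] = (0.5,)
    n_repeats: int = 10
    methods: tuple[str, ...] = METHODS
    m: int = 8
    eta: float = 0.7
    base_seed: int = 0
    filter_n_genes: int = 50
    en_mix: float = 0.5
    selection_tol: float = 1e-8
    options: OptimizerOptions | None = None
    grid: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if not self.methods:
            raise ValueError("methods must be non-empty")
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")


def _eval_method(
    method: str,
    train: ExpressionDataset,
    test: ExpressionDataset,
    cfg: ExperimentConfig,
    seed: int,
) -> tuple[float, np.ndarray]:
    """Fit one method on the split; return (test accuracy, selected genes)."""
    if method == "ours":
        model, sel, _ = fit_pipeline(
            train,
            m=cfg.m,
            eta=cfg.eta,
            grid=cfg.grid,
            seed=seed,
            options=cfg.options,
            selection_tol=cfg.selection_tol,
        )
        acc = float((model.predict(test.matrix) == test.labels).mean())
        return acc, sel.selected
    if method in ("l1", "elastic_net"):
        model, _ = cv_fit_penalized(
            train,
            penalty=method,
            en_mix=cfg.en_mix,
            grid=cfg.grid,
            seed=seed,
            options=cfg.options,
        )
        acc = float((model.predict(test.matrix) == test.labels).mean())
        selected = np.flatnonzero(np.abs(model.W[:, 0]) > cfg.selection_tol)
        return acc, selected
    acc, selected = filter_then_classify(
        train, test, method=method, n_select=cfg.filter_n_genes, seed=seed
    )
    return acc, selected


def run_comparison(
    ds: ExpressionDataset,
    cfg: ExperimentConfig | None = None,
    truth: np.ndarray | None = None,
) -> pd.DataFrame:
    """The repeated-split comparison table.

    Returns one row per (train_fraction, method) with accuracy mean/SD over
    repeats, mean selected-gene count and — when ``truth`` is given — the
    mean number of truly relevant genes recovered.
    """
    cfg = cfg or ExperimentConfig()
    records = []
    for frac in cfg.train_fractions:
        per_method: dict[str, dict[str, list]] = {
            meth: {"acc": [], "n_sel": [], "n_rec": []} for meth in cfg.methods
        }
        for r in range(cfg.n_repeats):
            seed = cfg.base_seed + r
            train, test = split_train_test(
                ds, SplitSpec(train_fraction=frac, stratified=True, seed=seed)
            )
            for meth in cfg.methods:
                acc, selected = _eval_method(meth, train, test, cfg, seed)
                per_method[meth]["acc"].append(acc)
                n_sel, n_rec = (
                    selection_metrics(selected, truth)
                    if truth is not None
                    else (len(selected), np.nan)
                )
                per_method[meth]["n_sel"].append(n_sel)
                per_method[meth]["n_rec"].append(n_rec)
        for meth in cfg.methods:
            accs = np.asarray(per_method[meth]["acc"])
            rec = {
                "train_fraction": frac,
                "method": meth,
                "accuracy_mean": float(accs.mean()),
                "accuracy_sd": float(accs.std()),
                "n_selected_mean": float(np.mean(per_method[meth]["n_sel"])),
            }
            if truth is not None:
                rec["n_relevant_recovered_mean"] = float(
                    np.mean(per_method[meth]["n_rec"])
                )
            records.append(rec)
    return pd.DataFrame.from_records(records)


def sweep_num_tasks(
    ds: ExpressionDataset,
    k_values: Sequence[int] = (2, 4, 6, 8, 10),
    cfg: ExperimentConfig | None = None,
    train_fraction: float = 0.5,
) -> pd.DataFrame:
    """Mean test accuracy of the ensemble as the task count k varies.

    All k share the same splits (and per-repeat seeds), so the sweep isolates
    the effect of the ensemble size.
    """
    cfg = cfg or ExperimentConfig()
    if any(k < 1 for k in k_values):
        raise ValueError("all k values must be >= 1")
    splits = [
        split_train_test(
            ds,
            SplitSpec(
                train_fraction=train_fraction, stratified=True, seed=cfg.base_seed + r
            ),
        )
        for r in range(cfg.n_repeats)
    ]
    records = []
    for k in k_values:
        accs = []
        for r, (train, test) in enumerate(splits):
            model, _, _ = fit_pipeline(
                train,
                m=k,
                eta=cfg.eta,
                grid=cfg.grid,
                seed=cfg.base_seed + r,
                options=cfg.options,
            )
            accs.append(float((model.predict(test.matrix) == test.labels).mean()))
        accs = np.asarray(accs)
        records.append(
            {
                "k": int(k),
                "accuracy_mean": float(accs.mean()),
                "accuracy_sd": float(accs.std()),
            }
        )
    return pd.DataFrame.from_records(records)
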