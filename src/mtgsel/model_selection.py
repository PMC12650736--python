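"""Penalty-weight selection by stratified 5-fold cross-validation.

The grid of candidate lambdas is log-spaced up to lambda_max, the smallest
penalty at which the all-zero model is optimal, so the null model is always a
candidate.  Within each fold the task subsets are redrawn from the fold's
training portion; fits proceed along the grid from the largest lambda down,
warm-starting each fit from the previous one.  The chosen lambda minimizes the
mean held-out log-loss, with ties broken toward the larger (sparser) value.
The same lambda is shared by all tasks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .io_data import ExpressionDataset, standardize_apply, standardize_fit
from .mtl_core import MultiTaskModel, SelectionResult, predict_logits, select_genes
from .optimizer import OptimizerOptions, fit, lambda_max
from .task_sampling import draw_task_subsets

__all__ = ["CVResult", "default_lambda_grid", "cv_select_lambda", "fit_pipeline"]

GRID_SIZE = 20
GRID_RATIO = 1e-3  # smallest grid point relative to lambda_max


@dataclass
class CVResult:
    """Cross-validation record: the grid, per-lambda mean scores, the choice."""

    grid: np.ndarray
    mean_val_logloss: np.ndarray
    mean_val_accuracy: np.ndarray
    chosen_lambda: float
    fold_assignments: np.ndarray


def _fold_seed(seed: int, fold: int) -> int:
    return (seed + 100003 * (fold + 1)) % (2**31)


def _check_grid(grid: np.ndarray) -> np.ndarray:
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("lambda grid must be non-empty")
    if np.any(grid <= 0):
        raise ValueError("lambda grid values must be strictly positive")
    if np.any(np.diff(grid) < 0):
        raise ValueError("lambda grid must be sorted ascending")
    return grid


def default_lambda_grid(
    train: ExpressionDataset,
    m: int = 8,
    eta: float = 0.7,
    seed: int = 0,
    num: int = GRID_SIZE,
    ratio: float = GRID_RATIO,
    standardize: bool = True,
) -> np.ndarray:
    """Log-spaced grid from ratio*lambda_max to lambda_max on the training data."""
    X = train.matrix
    if standardize:
        mean, scale = standardize_fit(X)
        X = standardize_apply(X, mean, scale)
    tc = draw_task_subsets(X, m=m, eta=eta, seed=seed, y=train.y_signed)
    lmax = lambda_max(tc)
    return np.geomspace(ratio * lmax, lmax, num)


def _signed01(y01: np.ndarray) -> np.ndarray:
    return 2 * np.asarray(y01, dtype=int) - 1


def _logloss(logits: np.ndarray, y_signed: np.ndarray) -> float:
    return float(np.logaddexp(0.0, -y_signed * logits).mean())


def cv_select_lambda(
    train: ExpressionDataset,
    grid: np.ndarray | None = None,
    m: int = 8,
    eta: float = 0.7,
    seed: int = 0,
    n_folds: int = 5,
    standardize: bool = True,
    options: OptimizerOptions | None = None,
) -> CVResult:
    """Select lambda for the multi-task ensemble by stratified k-fold CV."""
    if grid is None:
        grid = default_lambda_grid(train, m=m, eta=eta, seed=seed, standardize=standardize)
    grid = _check_grid(grid)

    X, y01 = train.matrix, train.labels
    n = train.n
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed % (2**31))
    losses = np.zeros((n_folds, grid.size))
    accs = np.zeros((n_folds, grid.size))
    fold_assignments = np.empty(n, dtype=int)
    for f, (tr, va) in enumerate(skf.split(X, y01)):
        fold_assignments[va] = f
        Xtr, Xva = X[tr], X[va]
        if standardize:
            mean, scale = standardize_fit(Xtr)
            Xtr = standardize_apply(Xtr, mean, scale)
            Xva = standardize_apply(Xva, mean, scale)
        ytr, yva = y01[tr], y01[va]
        if len(np.unique(yva)) < 2 or len(np.unique(ytr)) < 2:
            raise ValueError(f"fold {f} is missing a class")
        tc = draw_task_subsets(
            Xtr, m=m, eta=eta, seed=_fold_seed(seed, f), y=ytr
        )
        W = c = None
        yva_s = _signed01(yva)
        for g in range(grid.size - 1, -1, -1):  # descending, warm-started
            W, c, _ = fit(tc, grid[g], options=options, W0=W, c0=c)
            logits = predict_logits(W, c, Xva)
            losses[f, g] = _logloss(logits, yva_s)
            accs[f, g] = float(((logits > 0).astype(int) == yva).mean())
    mean_loss = losses.mean(axis=0)
    mean_acc = accs.mean(axis=0)
    # ties broken toward the larger (sparser) lambda
    best = mean_loss.min()
    chosen = float(grid[np.flatnonzero(mean_loss <= best + 1e-12)[-1]])
    return CVResult(
        grid=grid,
        mean_val_logloss=mean_loss,
        mean_val_accuracy=mean_acc,
        chosen_lambda=chosen,
        fold_assignments=fold_assignments,
    )


def fit_pipeline(
    train: ExpressionDataset,
    m: int = 8,
    eta: float = 0.7,
    grid: np.ndarray | None = None,
    seed: int = 0,
    n_folds: int = 5,
    standardize: bool = True,
    options: OptimizerOptions | None = None,
    selection_tol: float = 1e-8,
) -> tuple[MultiTaskModel, SelectionResult, CVResult]:
    """CV-select lambda, refit on the full training set, return the model.

    Fully deterministic given ``seed``: the fold shuffling, the per-fold task
    draws and the final task draw all derive from it.
    """
    cv = cv_select_lambda(
        train,
        grid=grid,
        m=m,
        eta=eta,
        seed=seed,
        n_folds=n_folds,
        standardize=standardize,
        options=options,
    )
    X = train.matrix
    mean = scale = None
    if standardize:
        mean, scale = standardize_fit(X)
        X = standardize_apply(X, mean, scale)
    tc = draw_task_subsets(X, m=m, eta=eta, seed=seed, y=train.y_signed)
    W, c, _ = fit(tc, cv.chosen_lambda, options=options)
    model = MultiTaskModel(
        W=W,
        c=c,
        lam=cv.chosen_lambda,
        gene_ids=list(train.gene_ids),
        feature_mean=mean,
        feature_scale=scale,
    )
    selection = select_genes(W, tol=selection_tol)
    return model, selection, cv
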