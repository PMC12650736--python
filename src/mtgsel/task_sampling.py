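"""Random subsampling of the training set into the tasks of the ensemble.

Each of the m tasks is an independent draw, without replacement, of a fraction
eta of the training samples (eta = 0.7 by default).  Tasks overlap with each
other; "without replacement" applies within one task only.  Draws are
stratified by class by default so that no task is degenerate single-class.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_data import ExpressionDataset

__all__ = ["TaskCollection", "draw_task_subsets"]


@dataclass
class TaskCollection:
    """The m subsampled tasks: shared X/y plus an m x nk index matrix."""

    X: np.ndarray  # n x d, the (already preprocessed) training matrix
    y: np.ndarray  # n signed labels in {-1, +1}
    subsets: np.ndarray  # m x nk integer sample indices
    eta: float
    seed: int | None = None
    _Xs: np.ndarray | None = field(default=None, repr=False, compare=False)
    _ys: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        self.subsets = np.asarray(self.subsets, dtype=int)
        if self.subsets.ndim != 2:
            raise ValueError("subsets must be an m x nk index matrix")
        if not set(np.unique(self.y).tolist()) <= {-1, 1}:
            raise ValueError("task labels must be signed {-1, +1}")
        for row in self.subsets:
            if len(np.unique(row)) != len(row):
                raise ValueError("a task subset contains duplicate indices")

    @property
    def m(self) -> int:
        return self.subsets.shape[0]

    @property
    def nk(self) -> int:
        return self.subsets.shape[1]

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]

    @property
    def Xs(self) -> np.ndarray:
        """Task design tensor of shape (m, nk, d); cached."""
        if self._Xs is None:
            self._Xs = self.X[self.subsets]
        return self._Xs

    @property
    def ys(self) -> np.ndarray:
        """Task label matrix of shape (m, nk); cached."""
        if self._ys is None:
            self._ys = self.y[self.subsets]
        return self._ys

    def task_X(self, k: int) -> np.ndarray:
        return self.X[self.subsets[k]]

    def task_y(self, k: int) -> np.ndarray:
        return self.y[self.subsets[k]]

    def subsets_to_json(self, path: str | Path) -> None:
        """Export the subset indices for exact experiment replay."""
        payload = {
            "eta": self.eta,
            "seed": self.seed,
            "subsets": self.subsets.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def _signed(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    vals = set(np.unique(y).tolist())
    if vals <= {-1, 1}:
        return y.astype(int)
    if vals <= {0, 1}:
        return (2 * y - 1).astype(int)
    raise ValueError(f"labels must be {{0,1}} or {{-1,+1}}, got {sorted(vals)}")


def _stratified_quota(y01: np.ndarray, nk: int) -> dict[int, int]:
    """Largest-remainder allocation of nk slots across classes, each >= 1."""
    classes, counts = np.unique(y01, return_counts=True)
    exact = counts / counts.sum() * nk
    base = np.floor(exact).astype(int)
    # guarantee at least one sample per class when there is room
    base = np.maximum(base, 1)
    while base.sum() > nk:
        j = int(np.argmax(base - exact))
        base[j] -= 1
    rem = exact - base
    while base.sum() < nk:
        j = int(np.argmax(rem))
        base[j] += 1
        rem[j] = -np.inf
    base = np.minimum(base, counts)
    return dict(zip(classes.tolist(), base.tolist()))


def draw_task_subsets(
    data: ExpressionDataset | np.ndarray,
    m: int = 8,
    eta: float = 0.7,
    seed: int = 0,
    y: np.ndarray | None = None,
    stratified: bool = True,
    max_redraws: int = 100,
) -> TaskCollection:
    """Draw the m task subsets, each of size round(eta * n).

    Parameters
    ----------
    data
        Either an :class:`~mtgsel.io_data.ExpressionDataset` or a raw n x d
        matrix (in which case ``y`` must be given).
    m, eta, seed
        Number of tasks, sampling rate in (0, 1], RNG seed.
    stratified
        Allocate each task's slots across classes in proportion to class
        frequency (largest-remainder rounding, at least one slot per class).
        With ``stratified=False`` draws are plain uniform without replacement
        and a single-class subset is redrawn up to ``max_redraws`` times.
    """
    if isinstance(data, ExpressionDataset):
        X = data.matrix
        ys = data.y_signed
    else:
        if y is None:
            raise ValueError("y is required when data is a raw matrix")
        X = np.asarray(data, dtype=float)
        ys = _signed(y)
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0.0 < eta <= 1.0:
        raise ValueError("eta must lie in (0, 1]")
    n = X.shape[0]
    nk = int(round(eta * n))
    if nk < 2:
        raise ValueError(f"round(eta*n) = {nk} < 2; subsets too small")

    rng = np.random.default_rng(seed)
    y01 = (ys > 0).astype(int)
    rows = np.empty((m, nk), dtype=int)
    if stratified:
        if len(np.unique(y01)) < 2:
            raise ValueError("stratified draws require both classes present")
        quota = _stratified_quota(y01, nk)
        members = {c: np.flatnonzero(y01 == c) for c in quota}
        for k in range(m):
            parts = [
                rng.choice(members[c], size=q, replace=False)
                for c, q in quota.items()
            ]
            rows[k] = rng.permutation(np.concatenate(parts))
    else:
        for k in range(m):
            for _ in range(max_redraws + 1):
                cand = rng.choice(n, size=nk, replace=False)
                if len(np.unique(y01[cand])) == 2:
                    rows[k] = cand
                    break
            else:
                raise RuntimeError(
                    f"task {k}: single-class subset after {max_redraws} redraws"
                )
    return TaskCollection(X=X, y=ys, subsets=rows, eta=eta, seed=seed)
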