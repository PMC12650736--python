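"""Mathematical core of the multi-task ensemble model.

The model fits m logistic regression tasks jointly.  Writing W for the d x m
weight matrix (column k = task k, row j = gene j) and c for the m biases, the
smooth part of the objective is the per-task-averaged logistic loss

    L(W, c) = sum_k (1/n_k) sum_i log(1 + exp(-y_ik (x_ik . W_k + c_k)))

and the penalty is the l2,1 norm over gene rows, lambda * sum_j ||W_j.||_2,
which zeroes whole rows and therefore gives every gene a shared in/out status
across all tasks.  Prediction averages the m task logits before the logistic
link; a gene is selected when its row norm is nonzero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.special import expit

from .task_sampling import TaskCollection

__all__ = [
    "MultiTaskModel",
    "SelectionResult",
    "smooth_loss",
    "objective",
    "gradient",
    "prox_l21",
    "row_norms",
    "predict_logits",
    "predict_proba",
    "predict_labels",
    "select_genes",
]

#: default tolerance above which a row norm counts as a selected gene;
#: the prox produces exact zeros, so this only guards float noise
SELECTION_TOL = 1e-8


def _margins(tc: TaskCollection, W: np.ndarray, c: np.ndarray) -> np.ndarray:
    """y_ik * (x_ik . W_k + c_k) as an (m, nk) array."""
    W = np.asarray(W, dtype=float)
    c = np.asarray(c, dtype=float)
    if W.shape != (tc.d, tc.m) or c.shape != (tc.m,):
        raise ValueError(
            f"expected W of shape {(tc.d, tc.m)} and c of shape {(tc.m,)}, "
            f"got {W.shape} and {c.shape}"
        )
    # tasks share one X, so one n x m GEMM plus a gather beats per-task matvecs
    Z = tc.X @ W + c  # n x m
    Zk = Z[tc.subsets, np.arange(tc.m)[:, None]]  # (m, nk)
    return tc.ys * Zk


def smooth_loss(tc: TaskCollection, W: np.ndarray, c: np.ndarray) -> float:
    """Per-task-averaged logistic loss; numerically stable via logaddexp."""
    M = _margins(tc, W, c)
    return float(np.logaddexp(0.0, -M).mean(axis=1).sum())


def l21_norm(W: np.ndarray) -> float:
    return float(np.linalg.norm(W, axis=1).sum())


def objective(
    tc: TaskCollection, W: np.ndarray, c: np.ndarray, lam: float
) -> float:
    """Smooth loss plus lambda * sum over gene rows of ||W_j.||_2."""
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    return smooth_loss(tc, W, c) + lam * l21_norm(np.asarray(W, dtype=float))


def gradient(
    tc: TaskCollection, W: np.ndarray, c: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Gradient of :func:`smooth_loss` w.r.t. (W, c).

    Column k of the returned Gw depends only on task k's data:
    Gw[:, k] = (1/n_k) X_k^T (-y_k * sigma(-margins_k)); gc analogous.
    """
    M = _margins(tc, W, c)
    R = (-tc.ys * expit(-M)) / tc.nk  # (m, nk)
    # scatter per-task residuals into n x m (indices are unique within a task)
    Rfull = np.zeros((tc.n, tc.m))
    cols = np.arange(tc.m)[:, None]
    Rfull[tc.subsets, cols] = R
    Gw = tc.X.T @ Rfull
    gc = R.sum(axis=1)
    return Gw, gc


def prox_l21(A: np.ndarray, theta: float) -> np.ndarray:
    """Row-wise block soft-thresholding: the proximal operator of the l2,1 norm.

    Returns the exact minimizer of (1/2)||W - A||_F^2 + theta * sum_j ||W_j||_2,
    namely W_j = max(0, 1 - theta/||A_j||_2) * A_j (0 when ||A_j||_2 = 0).
    """
    if theta < 0:
        raise ValueError("theta must be nonnegative")
    A = np.asarray(A, dtype=float)
    norms = np.linalg.norm(A, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    scale = np.maximum(0.0, 1.0 - theta / safe)
    scale[norms == 0] = 0.0
    return A * scale[:, None]


def row_norms(W: np.ndarray) -> np.ndarray:
    """Per-gene cross-task weight norms ||W_j.||_2."""
    return np.linalg.norm(np.asarray(W, dtype=float), axis=1)


@dataclass
class SelectionResult:
    """Per-gene row norms and the resulting selected gene set."""

    row_norms: np.ndarray
    selected: np.ndarray  # gene indices sorted by descending row norm
    tol: float

    @property
    def n_selected(self) -> int:
        return int(len(self.selected))


def select_genes(W: np.ndarray, tol: float = SELECTION_TOL) -> SelectionResult:
    """Genes whose cross-task row norm exceeds ``tol``, largest norm first."""
    if tol < 0:
        raise ValueError("tol must be nonnegative")
    norms = row_norms(W)
    idx = np.flatnonzero(norms > tol)
    order = np.lexsort((idx, -norms[idx]))
    return SelectionResult(row_norms=norms, selected=idx[order], tol=tol)


def predict_logits(W: np.ndarray, c: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Logit-averaged ensemble score: zbar_i = (1/m) sum_k (x_i . W_k + c_k)."""
    W = np.asarray(W, dtype=float)
    c = np.asarray(c, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.shape[1] != W.shape[0]:
        raise ValueError(
            f"X has {X.shape[1]} genes but the model expects {W.shape[0]}"
        )
    return (X @ W + c).mean(axis=1)


def predict_proba(W: np.ndarray, c: np.ndarray, X: np.ndarray) -> np.ndarray:
    """phat = sigma(zbar), elementwise logistic of the averaged logits."""
    return expit(predict_logits(W, c, X))


def predict_labels(
    W: np.ndarray, c: np.ndarray, X: np.ndarray, tau: float = 0.5
) -> np.ndarray:
    """Class 1 iff phat > tau (strict; ties go to class 0)."""
    if not 0.0 < tau < 1.0:
        raise ValueError("tau must lie in (0, 1)")
    return (predict_proba(W, c, X) > tau).astype(int)


@dataclass
class MultiTaskModel:
    """A fitted multi-task ensemble: weights, biases, penalty and threshold.

    ``feature_mean``/``feature_scale`` record the training-set z-scoring so
    that raw test matrices can be transformed identically at prediction time
    (``None`` when the model was fitted on unstandardized data).
    """

    W: np.ndarray
    c: np.ndarray
    lam: float
    tau: float = 0.5
    gene_ids: list[str] | None = None
    feature_mean: np.ndarray | None = None
    feature_scale: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.c = np.asarray(self.c, dtype=float)
        if self.W.ndim != 2 or self.c.ndim != 1:
            raise ValueError("W must be d x m and c a length-m vector")
        if self.W.shape[1] != self.c.shape[0]:
            raise ValueError("W column count must match length of c")
        if not 0.0 < self.tau < 1.0:
            raise ValueError("tau must lie in (0, 1)")

    @property
    def d(self) -> int:
        return self.W.shape[0]

    @property
    def m(self) -> int:
        return self.W.shape[1]

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.feature_mean is None:
            return X
        return (X - self.feature_mean) / self.feature_scale

    def predict_logits(self, X: np.ndarray) -> np.ndarray:
        return predict_logits(self.W, self.c, self.transform(X))

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return predict_proba(self.W, self.c, self.transform(X))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return predict_labels(self.W, self.c, self.transform(X), self.tau)

    def select_genes(self, tol: float = SELECTION_TOL) -> SelectionResult:
        return select_genes(self.W, tol)

    def to_dict(self) -> dict:
        return {
            "W": self.W.tolist(),
            "c": self.c.tolist(),
            "lambda": self.lam,
            "tau": self.tau,
            "gene_ids": self.gene_ids,
            "feature_mean": None
            if self.feature_mean is None
            else np.asarray(self.feature_mean).tolist(),
            "feature_scale": None
            if self.feature_scale is None
            else np.asarray(self.feature_scale).tolist(),
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()) + "\n")

    @classmethod
    def from_dict(cls, payload: dict) -> "MultiTaskModel":
        return cls(
            W=np.asarray(payload["W"], dtype=float),
            c=np.asarray(payload["c"], dtype=float),
            lam=float(payload["lambda"]),
            tau=float(payload.get("tau", 0.5)),
            gene_ids=payload.get("gene_ids"),
            feature_mean=None
            if payload.get("feature_mean") is None
            else np.asarray(payload["feature_mean"], dtype=float),
            feature_scale=None
            if payload.get("feature_scale") is None
            else np.asarray(payload["feature_scale"], dtype=float),
        )

    @classmethod
    def load(cls, path: str | Path) -> "MultiTaskModel":
        return cls.from_dict(json.loads(Path(path).read_text()))
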