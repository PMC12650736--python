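"""Proximal gradient descent (ISTA) with backtracking line search.

The solver alternates a gradient step on the smooth logistic loss with the
penalty's proximal operator.  The step length is 1/gamma; a candidate step is
accepted when the quadratic-majorizer sufficient-decrease condition

    L(W') <= L(W) + <grad L, W' - W> + (gamma/2) ||W' - W||^2

holds, otherwise gamma is grown by the factor alpha and the step retried.
Under this rule the penalized objective is non-increasing and, the problem
being convex, the iterates approach a global minimum.  Biases are never
penalized; they take the plain gradient step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import mtl_core
from .mtl_core import gradient, prox_l21, smooth_loss
from .task_sampling import TaskCollection

__all__ = [
    "OptimizerOptions",
    "OptimizerState",
    "GroupL21Penalty",
    "ElasticNetPenalty",
    "proximal_step",
    "fit",
    "lambda_max",
    "optimality_residual",
]


@dataclass(frozen=True)
class OptimizerOptions:
    """Solver controls.

    gamma0 : initial inverse step length at each outer iteration.
    alpha : backtracking growth factor for gamma (> 1).
    tol_rel : stop when the relative objective decrease falls below this.
    max_iters : iteration cap T.
    max_backtracks : retry cap within a single iteration.
    """

    gamma0: float = 1.0
    alpha: float = 2.0
    tol_rel: float = 1e-6
    max_iters: int = 1000
    max_backtracks: int = 50

    def __post_init__(self) -> None:
        if self.gamma0 <= 0:
            raise ValueError("gamma0 must be positive")
        if self.alpha <= 1:
            raise ValueError("alpha must exceed 1")


@dataclass
class OptimizerState:
    """Outcome of a solve: final gamma, iteration count, objective trace."""

    gamma: float
    t: int
    trace: np.ndarray
    converged: bool


class GroupL21Penalty:
    """lambda * sum_j ||W_j.||_2 over gene rows of the d x m weight matrix."""

    def __init__(self, lam: float):
        if lam < 0:
            raise ValueError("lambda must be nonnegative")
        self.lam = float(lam)

    def value(self, W: np.ndarray) -> float:
        return self.lam * mtl_core.l21_norm(W)

    def prox(self, A: np.ndarray, gamma: float) -> np.ndarray:
        return prox_l21(A, self.lam / gamma)


class ElasticNetPenalty:
    """lambda * (mix * ||w||_1 + (1 - mix)/2 * ||w||_2^2), elementwise.

    ``mix`` is the l1 fraction; mix = 1 recovers the plain lasso penalty.
    Used by the single-task baselines through the same solver.
    """

    def __init__(self, lam: float, l1_ratio: float = 0.5):
        if lam < 0:
            raise ValueError("lambda must be nonnegative")
        if not 0.0 <= l1_ratio <= 1.0:
            raise ValueError("l1_ratio must lie in [0, 1]")
        self.lam = float(lam)
        self.l1_ratio = float(l1_ratio)

    def value(self, W: np.ndarray) -> float:
        W = np.asarray(W, dtype=float)
        return self.lam * (
            self.l1_ratio * np.abs(W).sum()
            + 0.5 * (1.0 - self.l1_ratio) * float((W**2).sum())
        )

    def prox(self, A: np.ndarray, gamma: float) -> np.ndarray:
        A = np.asarray(A, dtype=float)
        t = self.lam * self.l1_ratio / gamma
        soft = np.sign(A) * np.maximum(np.abs(A) - t, 0.0)
        return soft / (1.0 + self.lam * (1.0 - self.l1_ratio) / gamma)


def proximal_step(
    tc: TaskCollection,
    W: np.ndarray,
    c: np.ndarray,
    gamma: float,
    lam: float,
) -> tuple[np.ndarray, np.ndarray]:
    """One forward-backward step at fixed gamma: A = W - (1/gamma) grad, then prox."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    Gw, gc = gradient(tc, W, c)
    W_next = prox_l21(W - Gw / gamma, lam / gamma)
    c_next = c - gc / gamma
    return W_next, c_next


def fit(
    tc: TaskCollection,
    lam: float,
    options: OptimizerOptions | None = None,
    penalty=None,
    W0: np.ndarray | None = None,
    c0: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, OptimizerState]:
    """Solve the penalized multi-task logistic problem from (W0, c0) = 0.

    Returns the weight matrix, the biases and an :class:`OptimizerState`
    whose objective trace is non-increasing.  A custom ``penalty`` object
    (``value``/``prox``) overrides the default row-group l2,1 penalty; warm
    starts may be passed via ``W0``/``c0``.
    """
    opts = options or OptimizerOptions()
    if penalty is None:
        penalty = GroupL21Penalty(lam)
    W = np.zeros((tc.d, tc.m)) if W0 is None else np.array(W0, dtype=float)
    c = np.zeros(tc.m) if c0 is None else np.array(c0, dtype=float)

    f = smooth_loss(tc, W, c)
    obj = f + penalty.value(W)
    if not np.isfinite(obj):
        raise FloatingPointError("non-finite objective at the starting point")
    trace = [obj]
    gamma = opts.gamma0
    converged = False
    t = 0
    for t in range(1, opts.max_iters + 1):
        Gw, gc = gradient(tc, W, c)
        # let the step re-grow, but start near the last accepted curvature so
        # a typical iteration needs at most one or two majorization checks
        gamma = max(opts.gamma0, gamma / opts.alpha)
        for _ in range(opts.max_backtracks + 1):
            W_new = penalty.prox(W - Gw / gamma, gamma)
            c_new = c - gc / gamma
            dW = W_new - W
            dc = c_new - c
            f_new = smooth_loss(tc, W_new, c_new)
            quad = (
                f
                + float((Gw * dW).sum())
                + float(gc @ dc)
                + 0.5 * gamma * (float((dW**2).sum()) + float(dc @ dc))
            )
            if f_new <= quad + 1e-12:
                break
            gamma *= opts.alpha
        else:
            raise RuntimeError(
                f"backtracking exceeded {opts.max_backtracks} retries "
                f"at iteration {t}"
            )
        W, c, f = W_new, c_new, f_new
        obj_new = f + penalty.value(W)
        if not np.isfinite(obj_new):
            raise FloatingPointError(f"non-finite objective at iteration {t}")
        trace.append(obj_new)
        rel = (obj - obj_new) / max(abs(obj), 1e-12)
        obj = obj_new
        if rel < opts.tol_rel:
            converged = True
            break
    state = OptimizerState(
        gamma=gamma, t=t, trace=np.asarray(trace), converged=converged
    )
    return W, c, state


def _optimal_biases_at_zero(tc: TaskCollection) -> np.ndarray:
    """Per-task intercepts minimizing the loss at W = 0 (log odds of the subset)."""
    pos = (tc.ys > 0).mean(axis=1)
    pos = np.clip(pos, 1e-12, 1 - 1e-12)
    return np.log(pos / (1.0 - pos))


def lambda_max(tc: TaskCollection, penalty: str = "l21", l1_ratio: float = 1.0) -> float:
    """Smallest lambda at which the all-zero weight matrix is optimal.

    Computed from the KKT condition at W = 0 with the biases at their
    unpenalized optimum: the penalty's dual norm of the gradient there.
    """
    c_star = _optimal_biases_at_zero(tc)
    Gw, _ = gradient(tc, np.zeros((tc.d, tc.m)), c_star)
    if penalty == "l21":
        return float(np.linalg.norm(Gw, axis=1).max())
    if penalty in ("l1", "elastic_net"):
        if l1_ratio <= 0:
            return float("inf")
        return float(np.abs(Gw).max() / l1_ratio)
    raise ValueError(f"unknown penalty {penalty!r}")


def optimality_residual(
    tc: TaskCollection, W: np.ndarray, c: np.ndarray, lam: float
) -> float:
    """First-order (subgradient) residual of the fitted point.

    For nonzero gene rows: ||grad_j + lam * W_j/||W_j|| ||_2; for zero rows:
    max(0, ||grad_j||_2 - lam); plus the bias gradient norm.  Zero exactly at
    a global minimizer.
    """
    Gw, gc = gradient(tc, W, c)
    norms = np.linalg.norm(W, axis=1)
    res = np.empty(W.shape[0])
    nz = norms > 0
    if nz.any():
        res[nz] = np.linalg.norm(
            Gw[nz] + lam * W[nz] / norms[nz, None], axis=1
        )
    z = ~nz
    if z.any():
        res[z] = np.maximum(0.0, np.linalg.norm(Gw[z], axis=1) - lam)
    return float(max(res.max(), np.abs(gc).max()))
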