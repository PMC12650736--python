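"""Comparison methods: penalized single-task logistic fits and filter pipelines.

Two embedded baselines — L1- and elastic-net-penalized logistic regression —
reuse the proximal-gradient engine with an elementwise soft-thresholding prox,
and the same 5-fold CV machinery for choosing lambda.  Two filter baselines —
ReliefF and mRMR — score genes before model fitting and hand a fixed-size top
panel to a (lightly ridge-stabilized) logistic classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .io_data import ExpressionDataset, standardize_apply, standardize_fit
from .mtl_core import MultiTaskModel, predict_logits
from .model_selection import (
    GRID_RATIO,
    GRID_SIZE,
    _check_grid,
    _logloss,
    _signed01,
)
from .optimizer import ElasticNetPenalty, OptimizerOptions, fit, lambda_max
from .task_sampling import TaskCollection, _signed

__all__ = [
    "FilterScores",
    "single_task_collection",
    "fit_penalized_single_task",
    "cv_fit_penalized",
    "relieff_scores",
    "mrmr_select",
    "filter_then_classify",
    "FILTER_GENE_GRID",
]

#: gene-count grid conventionally swept for the filter methods
FILTER_GENE_GRID = (10, 20, 30, 40, 50)


@dataclass
class FilterScores:
    """Output of a filter method: scores (ReliefF) or greedy order (mRMR)."""

    method: str
    scores: np.ndarray | None = None  # per-gene, higher = better (ReliefF)
    order: np.ndarray | None = None  # greedy selection order (mRMR)
    params: dict = field(default_factory=dict)

    def top(self, n: int) -> np.ndarray:
        if self.order is not None:
            if n > len(self.order):
                raise ValueError(f"only {len(self.order)} genes were ordered")
            return np.asarray(self.order[:n], dtype=int)
        # stable: ties broken by gene index
        idx = np.lexsort((np.arange(len(self.scores)), -self.scores))
        return idx[:n]


def single_task_collection(X: np.ndarray, y) -> TaskCollection:
    """Wrap a full dataset as one 'task' so the shared solver applies."""
    X = np.asarray(X, dtype=float)
    return TaskCollection(
        X=X,
        y=_signed(np.asarray(y)),
        subsets=np.arange(X.shape[0])[None, :],
        eta=1.0,
    )


def _en_ratio(penalty: str, en_mix: float) -> float:
    if penalty == "l1":
        return 1.0
    if penalty == "elastic_net":
        return float(en_mix)
    raise ValueError(f"unknown penalty {penalty!r}")


def fit_penalized_single_task(
    X: np.ndarray,
    y,
    penalty: str = "l1",
    lam: float = 1.0,
    en_mix: float = 0.5,
    options: OptimizerOptions | None = None,
    w0: np.ndarray | None = None,
    b0: float | None = None,
) -> tuple[np.ndarray, float]:
    """Minimize mean logistic loss + lambda*[mix*||w||_1 + (1-mix)/2*||w||_2^2].

    ``penalty="l1"`` is the mix = 1 special case.  Solved by the same
    proximal-gradient engine as the multi-task model, with the elementwise
    elastic-net prox.
    """
    tc = single_task_collection(X, y)
    pen = ElasticNetPenalty(lam, _en_ratio(penalty, en_mix))
    W0 = None if w0 is None else np.asarray(w0, dtype=float)[:, None]
    c0 = None if b0 is None else np.array([b0], dtype=float)
    W, c, _ = fit(tc, lam, options=options, penalty=pen, W0=W0, c0=c0)
    return W[:, 0], float(c[0])


def cv_fit_penalized(
    train: ExpressionDataset,
    penalty: str = "l1",
    en_mix: float = 0.5,
    grid: np.ndarray | None = None,
    seed: int = 0,
    n_folds: int = 5,
    standardize: bool = True,
    options: OptimizerOptions | None = None,
) -> tuple[MultiTaskModel, float]:
    """5-fold CV over a log-spaced lambda grid, then refit on all of train.

    Returns a single-column :class:`MultiTaskModel` (m = 1) and the chosen
    lambda; mirrors the multi-task pipeline's CV protocol exactly.
    """
    ratio = _en_ratio(penalty, en_mix)
    X, y01 = train.matrix, train.labels
    if grid is None:
        Xg = X
        if standardize:
            mg, sg = standardize_fit(X)
            Xg = standardize_apply(X, mg, sg)
        lmax = lambda_max(
            single_task_collection(Xg, train.y_signed), "l1", l1_ratio=ratio
        )
        grid = np.geomspace(GRID_RATIO * lmax, lmax, GRID_SIZE)
    grid = _check_grid(grid)

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed % (2**31))
    losses = np.zeros((n_folds, grid.size))
    for f, (tr, va) in enumerate(skf.split(X, y01)):
        Xtr, Xva = X[tr], X[va]
        if standardize:
            mean, scale = standardize_fit(Xtr)
            Xtr = standardize_apply(Xtr, mean, scale)
            Xva = standardize_apply(Xva, mean, scale)
        yva_s = _signed01(y01[va])
        w = b = None
        for g in range(grid.size - 1, -1, -1):
            w, b = fit_penalized_single_task(
                Xtr, y01[tr], penalty, grid[g], en_mix, options, w0=w, b0=b
            )
            losses[f, g] = _logloss(Xva @ w + b, yva_s)
    mean_loss = losses.mean(axis=0)
    chosen = float(grid[np.flatnonzero(mean_loss <= mean_loss.min() + 1e-12)[-1]])

    mean = scale = None
    Xr = X
    if standardize:
        mean, scale = standardize_fit(X)
        Xr = standardize_apply(X, mean, scale)
    w, b = fit_penalized_single_task(Xr, y01, penalty, chosen, en_mix, options)
    model = MultiTaskModel(
        W=w[:, None],
        c=np.array([b]),
        lam=chosen,
        gene_ids=list(train.gene_ids),
        feature_mean=mean,
        feature_scale=scale,
    )
    return model, chosen


def relieff_scores(
    X: np.ndarray,
    y,
    k_neighbors: int = 10,
    n_sample_iters: int | None = None,
    seed: int = 0,
) -> FilterScores:
    """Classic binary ReliefF gene weights.

    For each probed instance, its k nearest same-class neighbors ("hits") and
    k nearest opposite-class neighbors ("misses") are found by Euclidean
    distance over all genes; a gene is rewarded for differing toward misses
    and penalized for differing toward hits, with per-gene differences
    normalized by the gene's training range (zero-range genes score 0).  With
    ``n_sample_iters=None`` every instance is probed once, deterministically.
    """
    X = np.asarray(X, dtype=float)
    y01 = np.asarray(y)
    y01 = (y01 > 0).astype(int) if set(np.unique(y01)) <= {-1, 1} else y01.astype(int)
    n, d = X.shape
    counts = np.bincount(y01, minlength=2)
    if k_neighbors < 1 or k_neighbors > counts.min() - 1:
        raise ValueError(
            f"k_neighbors must lie in [1, min class size - 1] = [1, {counts.min() - 1}]"
        )
    rng = np.random.default_rng(seed)
    if n_sample_iters is None:
        probes = np.arange(n)
    else:
        probes = rng.choice(n, size=n_sample_iters, replace=True)

    rng_range = X.max(axis=0) - X.min(axis=0)
    safe_range = np.where(rng_range > 0, rng_range, 1.0)
    d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)

    scores = np.zeros(d)
    iters = len(probes)
    for i in probes:
        same = np.flatnonzero(y01 == y01[i])
        same = same[same != i]
        opp = np.flatnonzero(y01 != y01[i])
        hits = same[np.argsort(d2[i, same], kind="stable")[:k_neighbors]]
        misses = opp[np.argsort(d2[i, opp], kind="stable")[:k_neighbors]]
        diff_h = np.abs(X[i] - X[hits]) / safe_range
        diff_m = np.abs(X[i] - X[misses]) / safe_range
        scores += diff_m.sum(axis=0) / (len(misses) * iters)
        scores -= diff_h.sum(axis=0) / (len(hits) * iters)
    scores[rng_range == 0] = 0.0
    return FilterScores(
        method="relieff",
        scores=scores,
        params={"k_neighbors": k_neighbors, "n_sample_iters": n_sample_iters, "seed": seed},
    )


def _equal_frequency_bins(col: np.ndarray, n_bins: int) -> np.ndarray:
    edges = np.quantile(col, np.arange(1, n_bins) / n_bins)
    return np.searchsorted(edges, col, side="right")


def _mi(a: np.ndarray, b: np.ndarray) -> float:
    """Mutual information (nats) of two small integer-coded arrays."""
    na, nb = a.max() + 1, b.max() + 1
    joint = np.bincount(a * nb + b, minlength=na * nb).reshape(na, nb)
    joint = joint / joint.sum()
    pa = joint.sum(axis=1, keepdims=True)
    pb = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float((joint[nz] * np.log(joint[nz] / (pa @ pb)[nz])).sum())


def mrmr_select(
    X: np.ndarray, y, n_select: int, n_bins: int = 3
) -> FilterScores:
    """Greedy minimum-redundancy maximum-relevance (MID variant) gene ordering.

    Genes are discretized into ``n_bins`` equal-frequency bins; the first pick
    maximizes I(gene; label) and each next pick maximizes
    I(g; y) - (1/|S|) sum_{s in S} I(g; s).  Deterministic; ties break toward
    the lower gene index.  Relevance uses only bin ranks, so it is invariant
    to monotone transforms of the expression values.
    """
    X = np.asarray(X, dtype=float)
    y01 = np.asarray(y)
    y01 = (y01 > 0).astype(int) if set(np.unique(y01)) <= {-1, 1} else y01.astype(int)
    n, d = X.shape
    if n_select > d:
        raise ValueError(f"n_select = {n_select} exceeds gene count {d}")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    binned = np.column_stack(
        [_equal_frequency_bins(X[:, j], n_bins) for j in range(d)]
    )
    relevance = np.array([_mi(binned[:, j], y01) for j in range(d)])

    selected: list[int] = []
    redundancy = np.zeros(d)  # running sum of MI with already-selected genes
    remaining = np.ones(d, dtype=bool)
    for _ in range(n_select):
        if selected:
            crit = relevance - redundancy / len(selected)
        else:
            crit = relevance.copy()
        crit[~remaining] = -np.inf
        j = int(np.argmax(crit))  # argmax takes the lowest index on ties
        selected.append(j)
        remaining[j] = False
        if remaining.any():
            for g in np.flatnonzero(remaining):
                redundancy[g] += _mi(binned[:, g], binned[:, j])
    return FilterScores(
        method="mrmr",
        order=np.asarray(selected, dtype=int),
        params={"n_bins": n_bins, "relevance": relevance},
    )


def filter_then_classify(
    train: ExpressionDataset,
    test: ExpressionDataset,
    method: str = "relieff",
    n_select: int = 50,
    seed: int = 0,
    k_neighbors: int = 10,
    n_bins: int = 3,
    ridge: float = 1e-6,
) -> tuple[float, np.ndarray]:
    """Filter genes on the training data only, then classify the test set.

    The top ``n_select`` genes by the filter are fed to a logistic regression
    with a tiny ridge term (lambda2 = ``ridge`` on the mean loss) for
    numerical stability.  Returns (test accuracy, selected gene indices).
    """
    mean, scale = standardize_fit(train.matrix)
    Xtr = standardize_apply(train.matrix, mean, scale)
    Xte = standardize_apply(test.matrix, mean, scale)
    if method == "relieff":
        k = min(k_neighbors, int(np.bincount(train.labels, minlength=2).min()) - 1)
        fs = relieff_scores(Xtr, train.labels, k_neighbors=k, seed=seed)
    elif method == "mrmr":
        fs = mrmr_select(Xtr, train.labels, n_select=n_select, n_bins=n_bins)
    else:
        raise ValueError(f"unknown filter method {method!r}")
    top = fs.top(min(n_select, train.d))
    clf = LogisticRegression(
        penalty="l2",
        C=1.0 / (ridge * train.n),
        solver="lbfgs",
        max_iter=5000,
    )
    clf.fit(Xtr[:, top], train.labels)
    acc = float((clf.predict(Xte[:, top]) == test.labels).mean())
    return acc, top
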