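import numpy as np
import pytest

from mtgsel import ExpressionDataset, draw_task_subsets


def make_dataset(n=40, d=12, seed=0, signal=1.5, n_signal=3):
    """A small learnable dataset: first ``n_signal`` genes carry the labels."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, d))
    beta = np.zeros(d)
    beta[:n_signal] = signal
    p = 1.0 / (1.0 + np.exp(-(X @ beta)))
    labels = (rng.random(n) < p).astype(int)
    if labels.min() == labels.max():  # force both classes on tiny draws
        labels[0] = 1 - labels[0]
    return ExpressionDataset(
        matrix=X,
        sample_ids=[f"s{i}" for i in range(n)],
        gene_ids=[f"g{j}" for j in range(d)],
        labels=labels,
    )


@pytest.fixture
def small_dataset():
    return make_dataset()


@pytest.fixture
def small_tasks(small_dataset):
    return draw_task_subsets(small_dataset, m=3, eta=0.7, seed=0)


def random_tasks(n=15, d=6, m=3, seed=0):
    """Random signed-label tasks for solver-level tests."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, d))
    y = rng.choice([-1, 1], size=n)
    while len(np.unique(y)) < 2:
        y = rng.choice([-1, 1], size=n)
    return draw_task_subsets(X, m=m, eta=0.8, seed=seed, y=y)
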