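"""Synthetic high-dimension low-sample datasets with planted relevant genes.

Each simulated cohort draws sample rows i.i.d. from a multivariate normal with
AR(1) gene-gene correlation (Sigma_ab = rho^|a-b|, unit marginals), plants a
small set of relevant genes (20 by default) at uniformly random positions with
alternating-sign coefficients of fixed magnitude, and draws binary labels from
the logistic model y_i ~ Bernoulli(sigma(x_i . beta)).  The six standard
configurations S1-S6 cover n in {100, 200} crossed with d in {500, 1000, 2000}.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.special import expit

from .io_data import ExpressionDataset

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "PRESETS",
    "preset_config",
    "simulate_dataset",
    "selection_metrics",
]

#: (n samples, d genes) of the six standard simulated cohorts
PRESETS: dict[str, tuple[int, int]] = {
    "S1": (100, 500),
    "S2": (200, 500),
    "S3": (100, 1000),
    "S4": (200, 1000),
    "S5": (100, 2000),
    "S6": (200, 2000),
}


@dataclass(frozen=True)
class SimulationConfig:
    n: int
    d: int
    n_relevant: int = 20
    rho: float = 0.5  # AR(1) gene-gene correlation
    effect_size: float = 0.75  # |beta| on relevant genes
    seed: int = 0
    max_label_retries: int = 100

    def __post_init__(self) -> None:
        if self.n_relevant > self.d:
            raise ValueError("n_relevant cannot exceed d")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must lie in [0, 1)")
        if self.effect_size <= 0:
            raise ValueError("effect_size must be positive")


def preset_config(name: str, seed: int = 0, **overrides) -> SimulationConfig:
    """Config for one of the standard cohorts S1-S6."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    n, d = PRESETS[name]
    return replace(SimulationConfig(n=n, d=d, seed=seed), **overrides)


@dataclass
class SimulatedDataset:
    """A synthetic cohort plus its generating ground truth."""

    dataset: ExpressionDataset
    truth: np.ndarray  # sorted indices of the planted relevant genes
    beta: np.ndarray  # generating coefficients, nonzero exactly on truth

    def truth_to_json(self, path: str | Path) -> None:
        payload = {
            "truth": self.truth.tolist(),
            "beta": self.beta.tolist(),
            "gene_ids": list(self.dataset.gene_ids),
        }
        Path(path).write_text(json.dumps(payload) + "\n")


def _ar1_normal(rng: np.random.Generator, n: int, d: int, rho: float) -> np.ndarray:
    # stationary AR(1) recursion across gene index: unit marginal variance,
    # corr(a, b) = rho^|a-b|
    Z = rng.standard_normal((n, d))
    if rho == 0.0:
        return Z
    X = np.empty((n, d))
    X[:, 0] = Z[:, 0]
    s = np.sqrt(1.0 - rho**2)
    for j in range(1, d):
        X[:, j] = rho * X[:, j - 1] + s * Z[:, j]
    return X


def simulate_dataset(cfg: SimulationConfig) -> SimulatedDataset:
    """Generate one synthetic cohort; deterministic given ``cfg.seed``.

    If a label draw comes out single-class the labels (only) are redrawn, up
    to ``cfg.max_label_retries`` times.
    """
    rng = np.random.default_rng(cfg.seed)
    X = _ar1_normal(rng, cfg.n, cfg.d, cfg.rho)
    truth = np.sort(rng.choice(cfg.d, size=cfg.n_relevant, replace=False))
    signs = np.where(np.arange(cfg.n_relevant) % 2 == 0, 1.0, -1.0)
    beta = np.zeros(cfg.d)
    beta[truth] = cfg.effect_size * signs
    probs = expit(X @ beta)
    for _ in range(cfg.max_label_retries + 1):
        labels = (rng.random(cfg.n) < probs).astype(int)
        if 0 < labels.sum() < cfg.n:
            break
    else:
        raise RuntimeError(
            f"single-class labels after {cfg.max_label_retries} retries"
        )
    ds = ExpressionDataset(
        matrix=X,
        sample_ids=[f"sample{i:04d}" for i in range(cfg.n)],
        gene_ids=[f"gene{j:05d}" for j in range(cfg.d)],
        labels=labels,
        class_names=("0", "1"),
    )
    return SimulatedDataset(dataset=ds, truth=truth, beta=beta)


def selection_metrics(selected, truth) -> tuple[int, int]:
    """(number selected, number of those that are truly relevant)."""
    sel = set(int(j) for j in np.asarray(selected, dtype=int))
    tru = set(int(j) for j in np.asarray(truth, dtype=int))
    return len(sel), len(sel & tru)
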