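"""Independent reference solvers used only by the tests.

Each oracle takes a different algorithmic route than the package (Newton,
coordinate descent, subgradient descent, brute-force grid search) so that
agreement is evidence of correctness rather than shared code.
"""

from __future__ import annotations

import numpy as np


def sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


def newton_logistic(X, y01, ridge=0.0, max_iter=200, tol=1e-12):
    """Damped Newton on the mean logistic loss (intercept unpenalized).

    Returns (w, b).  ``ridge`` adds (ridge/2)*||w||^2 to the mean loss.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y01, dtype=float)
    n, d = X.shape
    Xa = np.column_stack([X, np.ones(n)])
    theta = np.zeros(d + 1)

    def loss(th):
        z = Xa @ th
        return float(
            np.mean(np.logaddexp(0.0, z) - y * z)
            + 0.5 * ridge * th[:d] @ th[:d]
        )

    cur = loss(theta)
    for _ in range(max_iter):
        p = sigmoid(Xa @ theta)
        g = Xa.T @ (p - y) / n
        g[:d] += ridge * theta[:d]
        Wdiag = p * (1 - p)
        H = (Xa * Wdiag[:, None]).T @ Xa / n
        H[np.arange(d), np.arange(d)] += ridge
        H[np.arange(d + 1), np.arange(d + 1)] += 1e-12
        step = np.linalg.solve(H, g)
        t = 1.0
        while t > 1e-12:
            cand = theta - t * step
            val = loss(cand)
            if val <= cur - 1e-4 * t * (g @ step):
                break
            t /= 2
        theta, new = cand, val
        if cur - new < tol:
            cur = new
            break
        cur = new
    return theta[:d], float(theta[d])


def elastic_net_cd(
    X, y01, lam, l1_ratio=1.0, max_sweeps=5000, tol=1e-12
):
    """Proximal coordinate descent for mean logistic loss + elastic net.

    Minimizes (1/n) sum log(1+exp(-y_s(xw+b))) + lam*(mix*|w|_1 +
    (1-mix)/2*|w|_2^2) by cycling coordinates with per-coordinate quadratic
    majorization (L_j = mean(x_j^2)/4); the intercept takes plain majorized
    steps.  Returns (w, b, objective).
    """
    X = np.asarray(X, dtype=float)
    y = 2.0 * np.asarray(y01) - 1.0
    n, d = X.shape
    w = np.zeros(d)
    b = 0.0
    Lj = np.maximum((X**2).mean(axis=0) / 4.0, 1e-12)

    def objective(w, b):
        z = X @ w + b
        return float(
            np.mean(np.logaddexp(0.0, -y * z))
            + lam * (l1_ratio * np.abs(w).sum() + 0.5 * (1 - l1_ratio) * w @ w)
        )

    z = X @ w + b
    prev = objective(w, b)
    for _ in range(max_sweeps):
        for j in range(d):
            g = np.mean(-y * sigmoid(-y * z) * X[:, j]) + lam * (1 - l1_ratio) * w[j]
            L = Lj[j] + lam * (1 - l1_ratio)
            u = w[j] - g / L
            t = lam * l1_ratio / L
            new = np.sign(u) * max(abs(u) - t, 0.0)
            if new != w[j]:
                z += (new - w[j]) * X[:, j]
                w[j] = new
        gb = np.mean(-y * sigmoid(-y * z))
        b_new = b - 4.0 * gb
        z += b_new - b
        b = b_new
        cur = objective(w, b)
        if prev - cur < tol:
            prev = cur
            break
        prev = cur
    return w, b, prev


def subgradient_descent(loss_grad, pen_value, pen_subgrad, W0, c0, n_iters, step0):
    """Plain subgradient descent with step0/sqrt(t) steps; returns best objective."""
    W, c = W0.copy(), c0.copy()
    best = np.inf
    for t in range(1, n_iters + 1):
        f, Gw, gc = loss_grad(W, c)
        obj = f + pen_value(W)
        best = min(best, obj)
        step = step0 / np.sqrt(t)
        W = W - step * (Gw + pen_subgrad(W))
        c = c - step * gc
    f, _, _ = loss_grad(W, c)
    best = min(best, f + pen_value(W))
    return best


def prox_l21_bruteforce(a: np.ndarray, theta: float, half_width=8.0, coarse=161, refine=3):
    """Grid minimizer of (1/2)||w - a||^2 + theta*||w||_2 for one short row.

    Iteratively refined axis grid search; independent of the closed form.
    """
    a = np.asarray(a, dtype=float)
    lo = a - half_width
    hi = a + half_width
    best = None
    for _ in range(refine + 1):
        axes = [np.linspace(l, h, coarse) for l, h in zip(lo, hi)]
        mesh = np.meshgrid(*axes, indexing="ij")
        P = np.stack([m.ravel() for m in mesh], axis=1)
        vals = 0.5 * ((P - a) ** 2).sum(axis=1) + theta * np.linalg.norm(P, axis=1)
        i = int(np.argmin(vals))
        best = P[i]
        span = (hi - lo) / (coarse - 1) * 2.0
        lo = best - span
        hi = best + span
    return best
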