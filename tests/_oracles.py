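"""Independent likelihood oracles for cross-checking the EM engine.

These deliberately avoid the package's EM/compiled-likelihood code path:
log-likelihoods are evaluated from branch products written out by hand or
via ``TreeModel.category_probabilities`` (itself checked against
hand-expanded values), and maximization is done by brute-force grid search.
"""

from __future__ import annotations

import numpy as np


def binomial_loglik(k: int, n: int, prob: np.ndarray) -> np.ndarray:
    prob = np.clip(prob, 1e-12, 1 - 1e-12)
    return k * np.log(prob) + (n - k) * np.log1p(-prob)


def grid_maximize_1d(loglik_fn, step: float = 1e-5) -> tuple[float, float]:
    """Full grid search over one parameter in [0, 1]."""
    grid = np.arange(step, 1.0, step)
    ll = loglik_fn(grid[:, None])
    i = int(np.argmax(ll))
    return float(grid[i]), float(ll[i])


def grid_maximize_coordinate(
    loglik_fn, k: int, step: float = 1e-4, start=None, max_sweeps: int = 200
) -> tuple[np.ndarray, float]:
    """Cyclic coordinate-wise full-grid maximization for k parameters.

    Each sweep scans a full 1-D grid (step ``step``) per coordinate holding
    the others fixed; stops when a sweep no longer changes any coordinate.
    """
    theta = np.full(k, 0.5) if start is None else np.asarray(start, dtype=float)
    grid = np.arange(step, 1.0, step)
    for _ in range(max_sweeps):
        changed = False
        for j in range(k):
            cand = np.tile(theta, (grid.size, 1))
            cand[:, j] = grid
            ll = loglik_fn(cand)
            best = grid[int(np.argmax(ll))]
            if abs(best - theta[j]) > step / 2:
                changed = True
            theta[j] = best
        if not changed:
            break
    return theta, float(np.max(loglik_fn(theta[None, :])))


def tree_loglik_fn(tree_model, counts):
    """Vectorized multinomial log-likelihood over parameter matrices,
    evaluated through category_probabilities row by row."""
    free = list(tree_model.free_names)

    def fn(theta_matrix: np.ndarray) -> np.ndarray:
        theta_matrix = np.atleast_2d(theta_matrix)
        out = np.empty(theta_matrix.shape[0])
        for r, row in enumerate(theta_matrix):
            probs = tree_model.category_probabilities(dict(zip(free, row)))
            ll = 0.0
            for tree, cats in counts.counts.items():
                for cat, kk in cats.items():
                    if kk > 0:
                        ll += kk * np.log(max(probs[tree][cat], 1e-300))
            out[r] = ll
        return out

    return fn


def independent_binomial_lr(k1, n1, k2, n2) -> float:
    """G² for equality of two binomial proportions (hand-rolled 2x2
    likelihood-ratio test; the classic oracle for the DQ instruction
    comparison)."""

    def term(k, n, p):
        ll = 0.0
        if k > 0:
            ll += k * np.log(k / n / p)
        if n - k > 0:
            ll += (n - k) * np.log((n - k) / n / (1 - p))
        return ll

    pooled = (k1 + k2) / (n1 + n2)
    return 2.0 * (term(k1, n1, pooled) + term(k2, n2, pooled))
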