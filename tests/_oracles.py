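"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately avoid the library's own code paths: enumeration,
double loops and empirical permutation nulls only.
"""

from __future__ import annotations

import numpy as np


def enumerate_dtw_cost(dist: np.ndarray) -> float:
    """Minimum path cost by exhaustive enumeration of all monotone paths.

    Paths start at (0,0), end at the opposite corner, and move by
    (1,0), (0,1) or (1,1). Exponential — only for tiny instances.
    """
    la, lb = dist.shape
    best = [np.inf]

    def walk(i: int, j: int, cost: float) -> None:
        cost += dist[i, j]
        if cost >= best[0]:
            return
        if (i, j) == (la - 1, lb - 1):
            best[0] = cost
            return
        if i + 1 < la and j + 1 < lb:
            walk(i + 1, j + 1, cost)
        if i + 1 < la:
            walk(i + 1, j, cost)
        if j + 1 < lb:
            walk(i, j + 1, cost)

    walk(0, 0, 0.0)
    return best[0]


def pooled_within_variance_double_loop(X: np.ndarray, labels) -> tuple[float, int]:
    """Pooled within-group variance by explicit per-sample double loop."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    labels = list(labels)
    groups = sorted(set(labels), key=str)
    n = X.shape[1]
    ss = 0.0
    for g in groups:
        idx = [i for i, l in enumerate(labels) if l == g]
        centroid = np.zeros(X.shape[0])
        for i in idx:
            centroid += X[:, i]
        centroid /= len(idx)
        for i in idx:
            for f in range(X.shape[0]):
                ss += (X[f, i] - centroid[f]) ** 2
    df = n - len(groups)
    return ss / df, df


def permutation_nes_zscores(
    z: np.ndarray,
    set_indices: list[np.ndarray],
    n_perm: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Empirical z-scores of member-sum statistics vs a permutation null.

    For each set, the observed sum of z over its members is standardized
    against sums over ``n_perm`` random same-size draws of gene labels.
    Sets of equal size share one null for speed; the null itself is pure
    resampling, independent of any analytic formula.
    """
    out = np.empty(len(set_indices))
    nulls: dict[int, tuple[float, float]] = {}
    for k, idx in enumerate(set_indices):
        n = len(idx)
        if n not in nulls:
            draws = np.empty(n_perm)
            for p in range(n_perm):
                draws[p] = z[rng.choice(z.shape[0], size=n, replace=False)].sum()
            nulls[n] = (draws.mean(), draws.std(ddof=1))
        mu, sd = nulls[n]
        out[k] = (z[idx].sum() - mu) / sd
    return out
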