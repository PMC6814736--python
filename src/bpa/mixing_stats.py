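"""Species/batch mixing statistics, classical MDS and dendrogram helpers."""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from scipy.stats import f as f_dist
from sklearn.metrics import adjusted_rand_score

logger = logging.getLogger(__name__)


@dataclass
class FTestResult:
    """Variance-ratio test of species mixing within cell types.

    F = (pooled within-dataset variance) / (pooled within-cell-type
    variance): values above 1 mean cells of the same cell type sit closer
    together than cells of the same dataset/species, i.e. datasets mix
    within cell types. The ratio is referred to an F distribution with
    (N - M_t, N - M_s) degrees of freedom, upper tail.
    """

    V_within_celltype: float
    V_within_dataset: float
    F: float
    df1: int
    df2: int
    p_value: float
    N: int
    M_t: int
    M_s: int
    orientation_note: str = (
        "F = V_within_dataset / V_within_celltype; F > 1 means datasets mix "
        "within cell types"
    )

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def _as_groups(labels) -> tuple[np.ndarray, int]:
    labels = np.asarray([str(x) for x in labels])
    codes = pd.factorize(labels)[0]
    return codes, int(codes.max()) + 1


def pooled_within_group_variance(matrix: np.ndarray, labels) -> tuple[float, int]:
    """Pooled squared Euclidean deviation from group centroids, over N - M df.

    ``matrix`` is features x samples. With one feature this reduces to the
    textbook within-group mean square of one-way ANOVA, and the degrees of
    freedom N - M match that convention for any feature count.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    codes, m = _as_groups(labels)
    n = X.shape[1]
    if codes.shape[0] != n:
        raise ValueError("labels must cover all samples")
    if n < 2:
        raise ValueError("need at least 2 samples")
    df = n - m
    if df < 1:
        raise ValueError(f"zero degrees of freedom: N={n}, M={m}")
    ss = 0.0
    for g in range(m):
        cols = X[:, codes == g]
        centroid = cols.mean(axis=1, keepdims=True)
        ss += float(((cols - centroid) ** 2).sum())
    return ss / df, df


def species_mixing_test(bpa, cell_type_labels, dataset_labels) -> FTestResult:
    """F-test for whether cell types are tighter than datasets/species.

    Accepts a BPAMatrix (test runs in NES space) or a plain features x
    samples array. p is the upper-tail F probability with (N - M_t, N - M_s)
    degrees of freedom.
    """
    X = bpa.nes if hasattr(bpa, "nes") else np.asarray(bpa, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    n = X.shape[1]
    _, m_t = _as_groups(cell_type_labels)
    _, m_s = _as_groups(dataset_labels)
    if m_t < 2 and m_s < 2:
        raise ValueError("need at least 2 cell types or 2 datasets")
    v_t, df1 = pooled_within_group_variance(X, cell_type_labels)
    v_s, df2 = pooled_within_group_variance(X, dataset_labels)
    if v_t == 0.0:
        f_stat = np.inf
        p = 0.0
        logger.warning("within-cell-type variance is 0; F diverges, p -> 0")
    else:
        f_stat = v_s / v_t
        p = float(f_dist.sf(f_stat, df1, df2))
    return FTestResult(
        V_within_celltype=float(v_t),
        V_within_dataset=float(v_s),
        F=float(f_stat),
        df1=df1,
        df2=df2,
        p_value=p,
        N=n,
        M_t=m_t,
        M_s=m_s,
    )


def classical_mds(matrix: np.ndarray, dims: int = 2) -> np.ndarray:
    """Classical (Torgerson) MDS of features x samples data.

    Euclidean distances -> double-centered Gram matrix -> top-``dims``
    eigenvectors scaled by sqrt(eigenvalue). Deterministic: each axis is
    oriented so its largest-magnitude loading is positive. Components with
    non-positive eigenvalues are unavailable; asking for more dimensions
    than there are positive eigenvalues is an error.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    n = X.shape[1]
    if dims < 1:
        raise ValueError("dims must be >= 1")
    if n < dims + 1:
        raise ValueError(f"need at least dims+1={dims + 1} samples, got {n}")
    d = np.sqrt(((X[:, :, None] - X[:, None, :]) ** 2).sum(axis=0))
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    b = (b + b.T) / 2.0
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(n, 1) * np.finfo(float).eps * max(abs(eigval[0]), 1.0)
    n_pos = int((eigval > tol).sum())
    if dims > n_pos:
        raise ValueError(
            f"requested {dims} dimensions but only {n_pos} positive eigenvalues"
        )
    if n_pos < len(eigval) and (eigval < -tol).any():
        warnings.warn("negative eigenvalues dropped (non-Euclidean residual)")
    emb = eigvec[:, :dims] * np.sqrt(eigval[:dims])
    for k in range(dims):
        i = np.argmax(np.abs(emb[:, k]))
        if emb[i, k] < 0:
            emb[:, k] = -emb[:, k]
    return emb


@dataclass
class SplitPurityResult:
    winner: str  # "a", "b", or "tie"
    ari_a: float
    ari_b: float


def dendrogram_split_purity(matrix: np.ndarray, labels_a, labels_b) -> SplitPurityResult:
    """Which labeling does the top dendrogram split follow?

    Average-linkage hierarchical clustering on Euclidean distances, cut at
    the root into two branches; returns the labeling with the higher
    adjusted Rand index against the two-branch partition.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    la = [str(x) for x in labels_a]
    lb = [str(x) for x in labels_b]
    if len(la) != X.shape[1] or len(lb) != X.shape[1]:
        raise ValueError("labelings must cover all samples")
    z = linkage(pdist(X.T, metric="euclidean"), method="average")
    two = fcluster(z, t=2, criterion="maxclust")
    ari_a = float(adjusted_rand_score(la, two))
    ari_b = float(adjusted_rand_score(lb, two))
    if np.isclose(ari_a, ari_b):
        winner = "tie"
    else:
        winner = "a" if ari_a > ari_b else "b"
    return SplitPurityResult(winner=winner, ari_a=ari_a, ari_b=ari_b)
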