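"""Similarity Network Fusion core.

Builds per-layer patient-similarity networks with a scaled exponential
Euclidean-distance kernel, fuses them by iterated cross-diffusion, and
clusters the fused network with normalized spectral clustering. Partition
agreement is scored by normalized mutual information (NMI).

Kernel. With d(i,j) the Euclidean distance between samples, m_i the mean
distance from i to its K nearest neighbours (self excluded) and
eps_ij = (m_i + m_j + d(i,j)) / 3, the affinity is

    W(i,j) = exp(-d(i,j)^2 / (alpha * eps_ij)),   i != j,

the raw diagonal is stored as 0 and W is symmetrized. This is the
formula-level scaled-exponential kernel; no Gaussian-density variant.

Fusion. For each layer a row-stochastic "status" matrix P (diagonal 1/2,
off-diagonal row mass 1/2) and a sparse "local affinity" S (row-normalized
restriction of W to each sample's K nearest neighbours) are formed; the
update P_v <- S_v (mean of the other layers' P) S_v^T is iterated with
re-symmetrization and re-normalization each round, and the fused network is
the symmetrized mean of the final status matrices. A single layer returns
its normalized status matrix without iteration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.linalg import eigh
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans
from sklearn.metrics import normalized_mutual_info_score

__all__ = [
    "SNFParams",
    "standardize_features",
    "affinity_matrix",
    "snf_fuse",
    "spectral_cluster",
    "nmi",
]


@dataclass(frozen=True)
class SNFParams:
    """Kernel scaling variance alpha, neighbourhood size K, iterations T.

    The study's tuning grids are alpha in {0.3, 0.35, ..., 0.8} and
    K in {10, ..., 30}; the operations accept any alpha > 0 and 1 <= K < n.
    T caps the fusion iterations (early stop when the fused matrix moves by
    less than `tol` in max norm).
    """

    alpha: float = 0.5
    K: int = 20
    T: int = 20
    tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.T < 1:
            raise ValueError("T must be >= 1")


def standardize_features(matrix: np.ndarray) -> np.ndarray:
    """Column z-scores (population SD); zero-variance columns map to zeros."""
    X = np.asarray(matrix, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples to standardize")
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    out = X - mean
    nz = sd > 0
    out[:, nz] /= sd[nz]
    out[:, ~nz] = 0.0
    return out


def affinity_matrix(matrix: np.ndarray, params: SNFParams) -> np.ndarray:
    """Scaled exponential similarity kernel on sample rows.

    Caller standardizes features. Diagonal 0, symmetric, non-negative.
    Coincident samples (d = 0) receive the kernel maximum 1.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    if params.K >= n:
        raise ValueError(f"K ({params.K}) must be < number of samples ({n})")
    d = squareform(pdist(X))
    # mean distance to the K nearest neighbours, self excluded
    knn = np.sort(d, axis=1)[:, 1:params.K + 1]
    m = knn.mean(axis=1)
    eps = (m[:, None] + m[None, :] + d) / 3.0
    denom = params.alpha * eps
    ratio = np.divide(d * d, denom, out=np.zeros_like(d), where=denom > 0)
    W = np.exp(-ratio)
    np.fill_diagonal(W, 0.0)
    return (W + W.T) / 2.0


def _status_matrix(W: np.ndarray) -> np.ndarray:
    """Full-kernel normalization: diagonal 1/2, off-diagonal row mass 1/2."""
    n = W.shape[0]
    P = W.astype(float).copy()
    np.fill_diagonal(P, 0.0)
    rows = P.sum(axis=1)
    degenerate = rows <= 0
    if degenerate.any() and n > 1:
        P[degenerate] = 1.0
        np.fill_diagonal(P, 0.0)
        rows = P.sum(axis=1)
    P = P / (2.0 * rows[:, None])
    np.fill_diagonal(P, 0.5)
    return P


def _local_affinity(W: np.ndarray, K: int) -> np.ndarray:
    """Row-normalized restriction of W to each sample's K nearest neighbours.

    Neighbours ranked by affinity (descending), self excluded, ties broken
    by sample index (stable).
    """
    n = W.shape[0]
    S = np.zeros_like(W, dtype=float)
    for i in range(n):
        order = np.argsort(-W[i], kind="stable")
        order = order[order != i][:K]
        mass = W[i, order].sum()
        if mass > 0:
            S[i, order] = W[i, order] / mass
        else:
            S[i, order] = 1.0 / len(order)
    return S


def snf_fuse(affinities: Sequence[np.ndarray], params: SNFParams) -> np.ndarray:
    """Cross-diffusion fusion of per-layer affinity matrices.

    Returns the fused sample-similarity matrix (symmetric, non-negative).
    """
    mats = [np.asarray(W, dtype=float) for W in affinities]
    if not mats:
        raise ValueError("need at least one affinity matrix")
    n = mats[0].shape[0]
    for W in mats:
        if W.shape != (n, n):
            raise ValueError("affinity matrices must share the same sample set")
    if len(mats) == 1:
        P = _status_matrix(mats[0])
        return (P + P.T) / 2.0
    Ps = [_status_matrix(W) for W in mats]
    Ss = [_local_affinity(W, params.K) for W in mats]
    m = len(mats)
    fused_prev = np.mean(Ps, axis=0)
    for _ in range(params.T):
        new: list[np.ndarray] = []
        for v in range(m):
            other = (np.sum(Ps, axis=0) - Ps[v]) / (m - 1)
            P = Ss[v] @ other @ Ss[v].T
            P = (P + P.T) / 2.0
            new.append(_status_matrix(P))
        Ps = new
        fused = np.mean(Ps, axis=0)
        if np.max(np.abs(fused - fused_prev)) < params.tol:
            fused_prev = fused
            break
        fused_prev = fused
    F = (fused_prev + fused_prev.T) / 2.0
    return F


def spectral_cluster(network: np.ndarray, k: int, seed: int = 0) -> np.ndarray:
    """Normalized spectral clustering of a symmetric non-negative network.

    Embeds samples with the k leading eigenvectors of the symmetrically
    normalized affinity, row-normalizes, and partitions with seeded k-means
    (10 restarts, best inertia). Cluster labels are 1..k. Deterministic
    given the seed.
    """
    W = np.asarray(network, dtype=float)
    n = W.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must lie in [1, {n}], got {k}")
    if k == 1:
        return np.ones(n, dtype=int)
    if k == n:
        return np.arange(1, n + 1, dtype=int)
    W = (W + W.T) / 2.0
    deg = W.sum(axis=1)
    deg[deg <= 0] = 1e-12
    dinv = 1.0 / np.sqrt(deg)
    M = dinv[:, None] * W * dinv[None, :]
    M = (M + M.T) / 2.0
    _, vecs = eigh(M, subset_by_index=[n - k, n - 1])
    norms = np.linalg.norm(vecs, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    U = vecs / norms
    km = KMeans(n_clusters=k, n_init=10, random_state=int(seed))
    return km.fit_predict(U) + 1


def nmi(a: Sequence[int], b: Sequence[int]) -> float:
    """Normalized mutual information of two partitions, in [0, 1].

    Geometric-mean normalization; a partition with a single cluster has
    zero entropy and scores 0 by the 0/0 := 0 convention. Invariant to
    cluster relabeling and symmetric in its arguments.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"partition lengths differ: {a.shape} vs {b.shape}")
    if len(np.unique(a)) < 2 or len(np.unique(b)) < 2:
        return 0.0
    return float(normalized_mutual_info_score(a, b, average_method="geometric"))
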