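"""Network-consistency feature ranking (rSNF) and SNF hyperparameter tuning.

rSNF scores every multi-omics feature by how well a patient network built
from that feature alone reproduces the cluster structure of the SNF-fused
network: the fused network over all layers is spectrally clustered into as
many clusters as there are phenotype classes, each single-feature network
is clustered the same way, and the feature's consistency score is the NMI
between the two partitions. Higher scores mean the feature contributes
more of the overall network structure.

Hyperparameters (alpha, K) of the similarity kernel are chosen over grids
by repeated stratified cross-validation: on each fold-training subset the
fused network is built and clustered, and its NMI against the true
phenotype labels is the tuning objective (clustering is transductive on
the training portion; validation folds are unused, since the fusion has
no out-of-sample extension).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.model_selection import RepeatedStratifiedKFold

from .io import LabelVector, MultiOmicsDataset
from .metrics import RankedList
from .snf import SNFParams, affinity_matrix, nmi, snf_fuse, spectral_cluster, standardize_features
from .utils import derive_seed

__all__ = [
    "ALPHA_GRID",
    "K_GRID",
    "TuningReport",
    "tune_snf_hyperparams",
    "rsnf_rank",
    "fused_clustering",
]

# Default tuning grids: alpha in {0.3, 0.35, ..., 0.8}, K in {10, ..., 30}.
ALPHA_GRID: tuple[float, ...] = tuple(np.round(np.arange(0.30, 0.801, 0.05), 2))
K_GRID: tuple[int, ...] = tuple(range(10, 31))


@dataclass(frozen=True)
class TuningReport:
    """Grid search record: mean NMI per (alpha, K) and the chosen point."""

    alpha_grid: tuple[float, ...]
    k_grid: tuple[int, ...]
    mean_nmi: dict[tuple[float, int], float]
    chosen: SNFParams

    def as_dict(self) -> dict:
        return {
            "alpha_grid": list(self.alpha_grid),
            "k_grid": list(self.k_grid),
            "mean_nmi": [
                {"alpha": a, "K": k, "nmi": v} for (a, k), v in self.mean_nmi.items()
            ],
            "chosen": {"alpha": self.chosen.alpha, "K": self.chosen.K},
        }


def _layer_views(dataset: MultiOmicsDataset, rows: np.ndarray | None):
    for layer in dataset.layers:
        X = layer.values if rows is None else layer.values[rows]
        yield layer, X


def fused_clustering(dataset: MultiOmicsDataset, params: SNFParams,
                     n_clusters: int, seed: int,
                     rows: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Fused network and its spectral clustering on the given sample rows."""
    affinities = [
        affinity_matrix(standardize_features(X), params)
        for _, X in _layer_views(dataset, rows)
    ]
    fused = snf_fuse(affinities, params)
    clusters = spectral_cluster(fused, n_clusters, seed=seed)
    return fused, clusters


def tune_snf_hyperparams(dataset: MultiOmicsDataset,
                         labels: LabelVector | None = None,
                         alpha_grid: Sequence[float] = ALPHA_GRID,
                         k_grid: Sequence[int] = K_GRID,
                         cv_repeats: int = 10,
                         cv_folds: int = 5,
                         seed: int = 0) -> TuningReport:
    """Choose (alpha, K) maximizing mean fold-training NMI vs true labels.

    Ties break to the smallest K, then the smallest alpha. Per-fold
    distance structure is shared across the grid, so the search cost is
    dominated by the clustering step.
    """
    if labels is None:
        labels = dataset.labels
    if not alpha_grid or not k_grid:
        raise ValueError("grids must be non-empty")
    alpha_grid = tuple(sorted(float(a) for a in alpha_grid))
    k_grid = tuple(sorted(int(k) for k in k_grid))
    y = labels.codes()
    n_clusters = labels.n_classes

    cv = RepeatedStratifiedKFold(n_splits=cv_folds, n_repeats=cv_repeats,
                                 random_state=derive_seed(seed, "tune_cv"))
    scores: dict[tuple[float, int], list[float]] = {
        (a, k): [] for a in alpha_grid for k in k_grid
    }
    for fold_i, (tr, _val) in enumerate(cv.split(np.zeros(len(y)), y)):
        if max(k_grid) >= len(tr):
            raise ValueError(
                f"K={max(k_grid)} must be < fold-training size ({len(tr)})"
            )
        Xs = [standardize_features(X[tr]) for _, X in _layer_views(dataset, None)]
        for a in alpha_grid:
            for k in k_grid:
                params = SNFParams(alpha=a, K=k)
                affs = [affinity_matrix(X, params) for X in Xs]
                fused = snf_fuse(affs, params)
                clusters = spectral_cluster(
                    fused, n_clusters, seed=derive_seed(seed, "tune_cluster", fold_i))
                scores[(a, k)].append(nmi(clusters, y[tr]))
    mean_nmi = {key: float(np.mean(v)) for key, v in scores.items()}
    if all(np.isnan(v) for v in mean_nmi.values()):
        raise ValueError("tuning objective is undefined on every grid point")
    # max NMI; ties -> smallest K, then smallest alpha
    best = min(mean_nmi, key=lambda ak: (-mean_nmi[ak], ak[1], ak[0]))
    chosen = SNFParams(alpha=best[0], K=best[1])
    return TuningReport(alpha_grid, k_grid, mean_nmi, chosen)


def rsnf_rank(dataset: MultiOmicsDataset, params: SNFParams,
              n_clusters: int | None = None, seed: int = 0,
              rows: np.ndarray | None = None) -> RankedList:
    """Rank all features by consistency with the fused-network clustering.

    For each feature f_i a patient network is built from f_i alone (same
    standardization and kernel as the multi-feature layers), spectrally
    clustered into `n_clusters` clusters, and scored by NMI against the
    fused-network clustering. Features are returned in descending score
    order; exact ties keep (layer order, feature index) order.
    ``rows`` restricts the computation to a sample subset (e.g. the
    training portion of a fold).
    """
    if n_clusters is None:
        n_clusters = dataset.labels.n_classes
    _, ref_clusters = fused_clustering(
        dataset, params, n_clusters, seed=derive_seed(seed, "fused"), rows=rows)
    feature_ids: list[str] = []
    scores: list[float] = []
    for layer, X in _layer_views(dataset, rows):
        Z = standardize_features(X)
        for j, fid in enumerate(layer.feature_ids):
            Wf = affinity_matrix(Z[:, j][:, None], params)
            cf = spectral_cluster(
                Wf, n_clusters, seed=derive_seed(seed, "feature", fid))
            feature_ids.append(fid)
            scores.append(nmi(cf, ref_clusters))
    if not feature_ids:
        raise ValueError("no features to rank")
    order = np.argsort(-np.asarray(scores), kind="stable")
    return RankedList(
        tuple(feature_ids[i] for i in order),
        tuple(float(scores[i]) for i in order),
        "rsnf",
    )
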