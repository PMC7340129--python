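"""Orchestration of the three integration paths and signature extraction.

juXT: a classifier on the juxtaposed multi-omics matrix with ANOVA-F
ranking, developed on TR and tested on TS. rSNF: the same juxtaposed
matrix ranked by network consistency against the SNF-fused network (with
per-split hyperparameter tuning unless fixed kernel parameters are
given), developed on TR and tested on TS. rSNFi: the juxtaposed matrix
restricted to the per-split intersection of the juXT and rSNF top-ranked
lists, developed on TS and tested on TS2 so that feature selection and
model training never share data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .dap import (
    DAPConfig,
    ExperimentResult,
    SplitResult,
    SplitScheme,
    aggregate_splits,
    develop_split,
    make_tr_ts_ts2_splits,
)
from .io import MultiOmicsDataset, juxtapose, layer_of
from .metrics import anova_f_rank
from .ranking import ALPHA_GRID, K_GRID, rsnf_rank, tune_snf_hyperparams
from .snf import SNFParams
from .utils import derive_seed

__all__ = [
    "INFConfig",
    "Signature",
    "INFResult",
    "intersect_top_features",
    "extract_signature",
    "layer_contribution",
    "run_single_mode",
    "run_inf",
]


@dataclass(frozen=True)
class INFConfig:
    dap: DAPConfig = field(default_factory=DAPConfig)
    layer_subset: tuple[str, ...] | None = None
    snf_params: SNFParams | None = None    # fixed (alpha, K); None -> tune per split
    alpha_grid: tuple[float, ...] = ALPHA_GRID
    k_grid: tuple[int, ...] = K_GRID
    tune_repeats: int = 10
    tune_folds: int = 5
    intersection_level: str = "split"      # split | bob

    def __post_init__(self) -> None:
        if self.intersection_level not in ("split", "bob"):
            raise ValueError(f"unknown intersection level {self.intersection_level!r}")


@dataclass(frozen=True)
class Signature:
    """Top-N features of a method's Borda-of-Bordas list."""

    method: str
    feature_ids: tuple[str, ...]
    nf: float      # median best feature count across splits (may be half-integer)
    n: int         # floor(nf): the number of features actually extracted

    def __post_init__(self) -> None:
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("signature features must be unique")


@dataclass(frozen=True)
class INFResult:
    experiments: dict[str, ExperimentResult]
    signatures: dict[str, Signature]
    layer_contributions: dict[str, dict[str, float]]
    intersections: tuple[tuple[str, ...], ...] = ()
    rsnfi_skipped: str | None = None
    tuned_params: tuple[SNFParams, ...] = ()


def intersect_top_features(juxt_split: SplitResult,
                           rsnf_split: SplitResult) -> tuple[str, ...]:
    """Intersection of the two split-level top lists, in juXT order.

    Each list is its split's Borda list truncated at that split's selected
    feature count. An empty intersection is an explicit error (enlarge the
    top lists); there is no silent fallback.
    """
    juxt_top = juxt_split.cv.borda.top(juxt_split.best_count)
    rsnf_top = set(rsnf_split.cv.borda.top(rsnf_split.best_count))
    inter = tuple(f for f in juxt_top if f in rsnf_top)
    if not inter:
        raise ValueError(
            f"split {juxt_split.split_id}: empty juXT/rSNF top-list intersection "
            f"(sizes {juxt_split.best_count} and {rsnf_split.best_count}); "
            "increase the top-list sizes")
    return inter


def extract_signature(result: ExperimentResult) -> Signature:
    """Top-N BoB features, N = floor of the median best count across splits."""
    n = int(np.floor(result.nf))
    return Signature(result.method, result.bob.top(n), result.nf, n)


def layer_contribution(signature: Signature,
                       layer_names: Sequence[str] | None = None) -> dict[str, float]:
    """Fraction of signature features contributed by each layer (sums to 1)."""
    if not signature.feature_ids:
        raise ValueError("signature is empty")
    names = list(layer_names) if layer_names is not None else []
    counts: dict[str, int] = {n: 0 for n in names}
    for f in signature.feature_ids:
        counts[layer_of(f)] = counts.get(layer_of(f), 0) + 1
    total = len(signature.feature_ids)
    return {name: c / total for name, c in counts.items()}


def _anova_builder(X: np.ndarray, feature_ids: tuple[str, ...]):
    def builder(dev_idx, split_seed, y_dev):
        X_dev = X[dev_idx]

        def rank_fn(rows):
            return anova_f_rank(X_dev[rows], y_dev[rows], feature_ids)

        return rank_fn

    return builder


def _rsnf_builder(dataset: MultiOmicsDataset, config: INFConfig,
                  tuned_out: list[SNFParams]):
    """Fold-ranking builder for the network-consistency path.

    aDAP precomputes one ranking on the split's full development rows and
    reuses it in every fold; fDAP recomputes the fused network, its
    clustering, and the per-feature scores inside every fold on the
    fold-training rows only.
    """
    n_clusters = dataset.labels.n_classes

    def builder(dev_idx, split_seed, y_dev):
        if config.snf_params is not None:
            params = config.snf_params
        else:
            sub = _subset_rows(dataset, dev_idx, y_dev)
            report = tune_snf_hyperparams(
                sub, alpha_grid=config.alpha_grid, k_grid=config.k_grid,
                cv_repeats=config.tune_repeats, cv_folds=config.tune_folds,
                seed=derive_seed(split_seed, "snf_tune"))
            params = report.chosen
        tuned_out.append(params)
        if config.dap.dap_flavor == "accelerated":
            precomputed = rsnf_rank(dataset, params, n_clusters,
                                    seed=derive_seed(split_seed, "rsnf"),
                                    rows=np.asarray(dev_idx))

            def rank_fn(rows):
                return precomputed

        else:
            def rank_fn(rows):
                return rsnf_rank(dataset, params, n_clusters,
                                 seed=derive_seed(split_seed, "rsnf"),
                                 rows=np.asarray(dev_idx)[rows])

        return rank_fn

    return builder


def _subset_rows(dataset: MultiOmicsDataset, rows, y_dev) -> MultiOmicsDataset:
    """Dataset restricted to the given rows, labels replaced by y_dev codes."""
    from .io import LabelVector, OmicsLayer

    rows = np.asarray(rows)
    sample_ids = tuple(dataset.sample_ids[i] for i in rows)
    layers = tuple(
        OmicsLayer(l.name, sample_ids, l.feature_ids, l.values[rows])
        for l in dataset.layers
    )
    classes = dataset.labels.classes
    labels = LabelVector(tuple(classes[c] for c in np.asarray(y_dev)),
                         sample_ids, classes)
    return MultiOmicsDataset(layers, labels)


def run_single_mode(dataset: MultiOmicsDataset, config: INFConfig,
                    mode: str, schemes: Sequence[SplitScheme] | None = None,
                    ) -> ExperimentResult:
    """One integration mode (juxt | rsnf | single-layer via layer_subset)."""
    subset = list(config.layer_subset) if config.layer_subset else None
    view_ds = dataset.subset_layers(subset) if subset else dataset
    view = juxtapose(dataset, subset)
    y = dataset.labels.codes()
    if schemes is None:
        schemes = make_tr_ts_ts2_splits(dataset.labels, config.dap.n_splits,
                                        seed=derive_seed(config.dap.seed, "splits"))
    feature_ids = view.feature_ids
    if mode in ("juxt", "single"):
        builder = _anova_builder(view.values, feature_ids)
    elif mode == "rsnf":
        builder = _rsnf_builder(view_ds, config, tuned_out=[])
    else:
        raise ValueError(f"unknown mode {mode!r}")
    results = [
        develop_split(view.values, y, feature_ids, s.tr, s.ts,
                      config.dap, builder, s.split_id, dataset.labels.n_classes)
        for s in schemes
    ]
    return aggregate_splits(mode, results)


def run_inf(dataset: MultiOmicsDataset, config: INFConfig | None = None) -> INFResult:
    """The full three-path workflow on one multi-omics dataset.

    Per split: the juXT and rSNF experiments are developed on TR and
    tested on TS; their top-list intersection defines the rSNFi feature
    universe, on which a fresh ANOVA-ranked experiment is developed on TS
    and tested on TS2. The three experiments are aggregated into BoB
    lists, signatures (top-floor(Nf) features) and per-layer contribution
    fractions. Deterministic under the master seed of the DAP config.
    """
    if config is None:
        config = INFConfig()
    subset = list(config.layer_subset) if config.layer_subset else None
    view_ds = dataset.subset_layers(subset) if subset else dataset
    if len(view_ds.layers) < 2:
        raise ValueError("integration modes need at least 2 layers")
    view = juxtapose(dataset, subset)
    y = dataset.labels.codes()
    n_classes = dataset.labels.n_classes
    feature_ids = view.feature_ids
    schemes = make_tr_ts_ts2_splits(dataset.labels, config.dap.n_splits,
                                    seed=derive_seed(config.dap.seed, "splits"))
    juxt_builder = _anova_builder(view.values, feature_ids)
    tuned: list[SNFParams] = []
    rsnf_builder = _rsnf_builder(view_ds, config, tuned)

    juxt_splits, rsnf_splits = [], []
    for scheme in schemes:
        juxt_splits.append(develop_split(
            view.values, y, feature_ids, scheme.tr, scheme.ts,
            config.dap, juxt_builder, scheme.split_id, n_classes))
        rsnf_splits.append(develop_split(
            view.values, y, feature_ids, scheme.tr, scheme.ts,
            config.dap, rsnf_builder, scheme.split_id, n_classes))

    experiments = {
        "juxt": aggregate_splits("juxt", juxt_splits),
        "rsnf": aggregate_splits("rsnf", rsnf_splits),
    }

    # rSNFi: the juxtaposed data restricted to the juXT/rSNF top-list
    # intersection, developed on TS and tested on TS2. The intersection is
    # split-local by default; the BoB-level variant intersects the two
    # aggregated lists truncated at floor(Nf).
    rsnfi_splits = []
    intersections: list[tuple[str, ...]] = []
    rsnfi_skipped: str | None = None
    col_of = {f: j for j, f in enumerate(feature_ids)}

    def _run_rsnfi(scheme: SplitScheme, inter: tuple[str, ...]) -> SplitResult:
        cols = [col_of[f] for f in inter]
        X_restricted = view.values[:, cols]
        inner_builder = _anova_builder(X_restricted, inter)
        return develop_split(X_restricted, y, inter, scheme.ts, scheme.ts2,
                             config.dap, inner_builder, scheme.split_id, n_classes)

    if config.intersection_level == "bob":
        nj = max(1, int(np.floor(experiments["juxt"].nf)))
        nr = max(1, int(np.floor(experiments["rsnf"].nf)))
        rsnf_top = set(experiments["rsnf"].bob.top(nr))
        inter = tuple(f for f in experiments["juxt"].bob.top(nj) if f in rsnf_top)
        if not inter:
            rsnfi_skipped = ("empty juXT/rSNF BoB top-list intersection; "
                            "increase the top-list sizes")
        else:
            intersections = [inter] * len(schemes)
            rsnfi_splits = [_run_rsnfi(s, inter) for s in schemes]
    else:
        for scheme, js, rs in zip(schemes, juxt_splits, rsnf_splits):
            try:
                inter = intersect_top_features(js, rs)
            except ValueError as err:
                rsnfi_skipped = str(err)
                break
            intersections.append(inter)
            rsnfi_splits.append(_run_rsnfi(scheme, inter))

    if rsnfi_skipped is None and rsnfi_splits:
        experiments["rsnfi"] = aggregate_splits("rsnfi", rsnfi_splits)
    else:
        intersections = []
        rsnfi_splits = []
    signatures = {m: extract_signature(r) for m, r in experiments.items()}
    contributions = {
        m: layer_contribution(sig, view_ds.layer_names)
        for m, sig in signatures.items() if sig.feature_ids
    }
    return INFResult(experiments, signatures, contributions,
                     tuple(intersections), rsnfi_skipped, tuple(tuned))
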