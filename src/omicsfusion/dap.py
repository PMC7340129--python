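"""Data Analysis Plan engine.

Reproducible predictive protocol in the MAQC/SEQC tradition: repeated
stratified 50/30/20 train/test/second-test splits, a stratified repeated
cross-validation schedule on the training portion with per-fold feature
ranking and an increasing feature-fraction schedule, Borda aggregation of
the fold-level ranked lists, model selection at the feature count
maximizing mean CV MCC, a single held-out evaluation, and a random-labels
sanity mode. All randomness flows through one master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import RepeatedStratifiedKFold, StratifiedShuffleSplit
from sklearn.svm import SVC

from .io import LabelVector
from .metrics import (
    RankedList,
    borda_aggregate,
    mcc,
    precision_recall,
    studentized_bootstrap_ci,
)
from .utils import derive_seed, largest_remainder, round_half_up

__all__ = [
    "SplitScheme",
    "ClassifierSpec",
    "DAPConfig",
    "MetricsRecord",
    "CVResult",
    "SplitResult",
    "ExperimentResult",
    "make_tr_ts_ts2_splits",
    "cv_feature_counts",
    "tune_lsvm_c",
    "fit_classifier",
    "FittedModel",
    "run_cv_experiment",
    "finalize_and_test",
    "run_dap",
]

RankFn = Callable[[np.ndarray], RankedList]


@dataclass(frozen=True)
class SplitScheme:
    """One stratified TR/TS/TS2 partition, as row indices into the dataset."""

    split_id: int
    tr: np.ndarray
    ts: np.ndarray
    ts2: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        parts = [set(self.tr.tolist()), set(self.ts.tolist()), set(self.ts2.tolist())]
        total = len(self.tr) + len(self.ts) + len(self.ts2)
        union = parts[0] | parts[1] | parts[2]
        if len(union) != total:
            raise ValueError(f"split {self.split_id}: partitions overlap")


@dataclass(frozen=True)
class ClassifierSpec:
    """Random Forest (500 trees, Gini) or linear SVM with a tuned C.

    The LSVM regularization C is tuned over {10^i, -2 <= i <= 3} within a
    10x stratified Monte-Carlo cross-validation at 50/50 proportions.
    """

    kind: str = "rf"
    n_trees: int = 500
    c_grid: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0, 100.0, 1000.0)
    mc_rounds: int = 10

    def __post_init__(self) -> None:
        if self.kind not in ("rf", "lsvm"):
            raise ValueError(f"unknown classifier kind {self.kind!r}")
        if not self.c_grid:
            raise ValueError("c_grid must be non-empty")


@dataclass(frozen=True)
class DAPConfig:
    n_splits: int = 10
    cv_repeats: int = 10
    cv_folds: int = 5
    feature_fractions: tuple[float, ...] = (5, 10, 25, 50, 75, 100)
    classifier: ClassifierSpec = field(default_factory=ClassifierSpec)
    ranking: str = "anova_f"          # anova_f | rsnf
    dap_flavor: str = "accelerated"   # accelerated (aDAP) | full (fDAP)
    random_labels: bool = False
    positive_class: int = 1           # class-code treated as positive (binary)
    seed: int = 0

    def __post_init__(self) -> None:
        fr = self.feature_fractions
        if any(not 0 < f <= 100 for f in fr) or list(fr) != sorted(fr):
            raise ValueError("feature fractions must be ascending and in (0, 100]")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.ranking not in ("anova_f", "rsnf"):
            raise ValueError(f"unknown ranking {self.ranking!r}")
        if self.dap_flavor not in ("accelerated", "full"):
            raise ValueError(f"unknown DAP flavor {self.dap_flavor!r}")


@dataclass(frozen=True)
class MetricsRecord:
    mcc: float
    precision: float
    recall: float
    context: dict = field(default_factory=dict)


@dataclass(frozen=True)
class CVResult:
    records: tuple[MetricsRecord, ...]
    borda: RankedList
    feature_counts: tuple[int, ...]
    best_count: int
    best_mean_mcc: float

    def mean_mcc(self) -> float:
        """Mean CV MCC at the selected feature count."""
        return self.best_mean_mcc

    def mean_mcc_overall(self) -> float:
        """Mean CV MCC over every (repeat, fold, feature-count) record."""
        return float(np.mean([r.mcc for r in self.records]))


@dataclass(frozen=True)
class SplitResult:
    split_id: int
    cv: CVResult
    test: MetricsRecord
    best_count: int


@dataclass(frozen=True)
class ExperimentResult:
    method: str
    splits: tuple[SplitResult, ...]
    bob: RankedList
    nf: float

    def best_counts(self) -> list[int]:
        return [s.best_count for s in self.splits]

    def cv_mccs(self) -> list[float]:
        return [s.cv.best_mean_mcc for s in self.splits]

    def test_mccs(self) -> list[float]:
        return [s.test.mcc for s in self.splits]

    def summary(self, ci_seed: int = 0) -> dict:
        """Headline metrics with 95% studentized bootstrap CIs (needs >=3 splits)."""
        def ci(vals, tag):
            if len(vals) < 3 or np.ptp(vals) == 0 and len(vals) < 3:
                return None
            try:
                iv = studentized_bootstrap_ci(vals, seed=derive_seed(ci_seed, "ci", tag))
            except ValueError:
                return None
            return [iv.lower, iv.upper]

        cv_prec = [float(np.mean([r.precision for r in s.cv.records])) for s in self.splits]
        cv_rec = [float(np.mean([r.recall for r in s.cv.records])) for s in self.splits]
        out = {
            "method": self.method,
            "n_splits": len(self.splits),
            "MCC_cv": float(np.mean(self.cv_mccs())),
            "MCC_cv_CI": ci(self.cv_mccs(), "mcc_cv"),
            "MCC_ts": float(np.mean(self.test_mccs())),
            "MCC_ts_CI": ci(self.test_mccs(), "mcc_ts"),
            "PREC_cv": float(np.mean(cv_prec)),
            "PREC_cv_CI": ci(cv_prec, "prec_cv"),
            "REC_cv": float(np.mean(cv_rec)),
            "REC_cv_CI": ci(cv_rec, "rec_cv"),
            "PREC_ts": float(np.mean([s.test.precision for s in self.splits])),
            "REC_ts": float(np.mean([s.test.recall for s in self.splits])),
            "Nf": self.nf,
        }
        return out


def make_tr_ts_ts2_splits(labels: LabelVector, n_splits: int = 10, seed: int = 0,
                          fractions: tuple[float, float, float] = (0.5, 0.3, 0.2),
                          ) -> list[SplitScheme]:
    """Stratified 50/30/20 sample partitions, repeated ``n_splits`` times.

    Per-class sizes follow largest-remainder apportionment of the
    fractions, so each partition's class mix tracks the full dataset
    within one sample per class.
    """
    y = labels.codes()
    classes, counts = np.unique(y, return_counts=True)
    small = classes[counts < 3]
    if small.size:
        raise ValueError(
            f"class {labels.classes[small[0]]!r} has fewer than 3 samples; "
            "cannot populate TR/TS/TS2"
        )
    schemes = []
    for s in range(n_splits):
        split_seed = derive_seed(seed, "split", s)
        rng = np.random.default_rng(split_seed)
        parts: list[list[int]] = [[], [], []]
        for c in classes:
            idx = np.flatnonzero(y == c)
            rng.shuffle(idx)
            sizes = largest_remainder(fractions, len(idx))
            start = 0
            for p, size in enumerate(sizes):
                parts[p].extend(idx[start:start + size].tolist())
                start += size
        schemes.append(SplitScheme(
            split_id=s,
            tr=np.sort(np.array(parts[0], dtype=int)),
            ts=np.sort(np.array(parts[1], dtype=int)),
            ts2=np.sort(np.array(parts[2], dtype=int)),
            seed=split_seed,
        ))
    return schemes


def cv_feature_counts(total_features: int,
                      fractions: Sequence[float] = (5, 10, 25, 50, 75, 100),
                      ) -> tuple[int, ...]:
    """Ascending feature counts from percentage fractions (min 1, dedup)."""
    if total_features < 1:
        raise ValueError("need at least one feature")
    counts = sorted({max(1, round_half_up(f / 100.0 * total_features))
                     for f in fractions})
    return tuple(counts)


def tune_lsvm_c(X: np.ndarray, y: np.ndarray, spec: ClassifierSpec,
                seed: int = 0) -> float:
    """Tune the LSVM C over the grid by Monte-Carlo validation MCC.

    10 stratified 50/50 resamples; mean validation MCC per C; ties break
    to the smallest C. Deterministic given the seed.
    """
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present to tune C")
    if counts.min() < 2:
        raise ValueError("every class needs >=2 samples for stratified resampling")
    if len(spec.c_grid) == 1:
        return float(spec.c_grid[0])
    splitter = StratifiedShuffleSplit(n_splits=spec.mc_rounds, train_size=0.5,
                                      random_state=seed)
    folds = list(splitter.split(X, y))
    best_c, best_score = None, -np.inf
    for C in sorted(spec.c_grid):
        scores = []
        for tr, val in folds:
            clf = SVC(kernel="linear", C=C)
            clf.fit(X[tr], y[tr])
            pred = clf.predict(X[val])
            scores.append(mcc(confusion_matrix(y[val], pred, labels=classes)))
        score = float(np.mean(scores))
        if score > best_score + 1e-12:
            best_c, best_score = C, score
    assert best_c is not None
    return float(best_c)


@dataclass
class FittedModel:
    """A fitted classifier that remembers its training feature order."""

    estimator: object
    feature_ids: tuple[str, ...]

    def predict(self, X: np.ndarray,
                feature_ids: Sequence[str] | None = None) -> np.ndarray:
        if feature_ids is not None:
            feature_ids = tuple(feature_ids)
            if feature_ids != self.feature_ids:
                if set(feature_ids) != set(self.feature_ids):
                    raise ValueError(
                        "prediction features do not match the training features")
                pos = {f: i for i, f in enumerate(feature_ids)}
                X = np.asarray(X)[:, [pos[f] for f in self.feature_ids]]
        elif np.asarray(X).shape[1] != len(self.feature_ids):
            raise ValueError(
                f"expected {len(self.feature_ids)} feature columns, "
                f"got {np.asarray(X).shape[1]}")
        return self.estimator.predict(np.asarray(X))


def fit_classifier(spec: ClassifierSpec, X: np.ndarray, y: np.ndarray,
                   feature_ids: Sequence[str], seed: int = 0) -> FittedModel:
    """Seeded, deterministic fit of the configured classifier."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    if spec.kind == "rf":
        est = RandomForestClassifier(
            n_estimators=spec.n_trees, criterion="gini",
            random_state=seed, n_jobs=1)
    else:
        C = tune_lsvm_c(X, y, spec, seed=derive_seed(seed, "lsvm_c"))
        est = SVC(kernel="linear", C=C, random_state=seed)
    est.fit(np.asarray(X), y)
    return FittedModel(est, tuple(feature_ids))


def _score(y_true: np.ndarray, y_pred: np.ndarray, n_classes: int,
           positive: int, context: dict) -> MetricsRecord:
    C = confusion_matrix(y_true, y_pred, labels=np.arange(n_classes))
    prec, rec = precision_recall(C, positive=positive if n_classes == 2 else 1)
    return MetricsRecord(mcc=mcc(C), precision=prec, recall=rec, context=context)


def run_cv_experiment(X_tr: np.ndarray, y_tr: np.ndarray,
                      feature_ids: Sequence[str], config: DAPConfig,
                      rank_fn: RankFn, seed: int = 0,
                      n_classes: int | None = None) -> CVResult:
    """Repeated stratified CV with per-fold ranking and a count schedule.

    ``rank_fn`` receives the fold-training row indices (into ``X_tr``) and
    must return a ranking of the full feature universe computed from those
    rows only (for the accelerated flavor it may return a precomputed
    training-set-level ranking unchanged). For every feature count of the
    schedule a classifier is fit on the fold-training top-k features and
    scored on the held-out fold. The fold-level lists are Borda-aggregated
    and the selected count maximizes mean CV MCC (ties to the smaller
    count).
    """
    X_tr = np.asarray(X_tr)
    y_tr = np.asarray(y_tr)
    feature_ids = tuple(feature_ids)
    if n_classes is None:
        n_classes = len(np.unique(y_tr))
    counts = cv_feature_counts(len(feature_ids), config.feature_fractions)
    col_of = {f: j for j, f in enumerate(feature_ids)}
    cv = RepeatedStratifiedKFold(
        n_splits=config.cv_folds, n_repeats=config.cv_repeats,
        random_state=derive_seed(seed, "cv"))
    records: list[MetricsRecord] = []
    fold_lists: list[RankedList] = []
    per_count_mcc: dict[int, list[float]] = {k: [] for k in counts}
    for fold_i, (tr, val) in enumerate(cv.split(X_tr, y_tr)):
        repeat, fold = divmod(fold_i, config.cv_folds)
        ranked = rank_fn(tr)
        if ranked.universe != frozenset(feature_ids):
            raise ValueError("rank_fn must rank the full feature universe")
        fold_lists.append(ranked)
        for k in counts:
            top = ranked.top(k)
            cols = [col_of[f] for f in top]
            model = fit_classifier(
                config.classifier, X_tr[np.ix_(tr, cols)], y_tr[tr], top,
                seed=derive_seed(seed, "clf", fold_i, k))
            pred = model.predict(X_tr[np.ix_(val, cols)])
            rec = _score(y_tr[val], pred, n_classes, config.positive_class,
                         {"repeat": repeat, "fold": fold, "n_features": k})
            records.append(rec)
            per_count_mcc[k].append(rec.mcc)
    borda = borda_aggregate(fold_lists)
    means = {k: float(np.mean(v)) for k, v in per_count_mcc.items()}
    best_count = min(means, key=lambda k: (-means[k], k))
    return CVResult(tuple(records), borda, counts, best_count, means[best_count])


def finalize_and_test(X_tr: np.ndarray, y_tr: np.ndarray,
                      X_ts: np.ndarray, y_ts: np.ndarray,
                      feature_ids: Sequence[str], borda: RankedList,
                      best_count: int, config: DAPConfig, seed: int = 0,
                      n_classes: int | None = None) -> MetricsRecord:
    """Retrain on the training set's top-`best_count` Borda features, score once."""
    feature_ids = tuple(feature_ids)
    if best_count > len(feature_ids):
        raise ValueError("best_count exceeds the feature universe")
    if n_classes is None:
        n_classes = len(np.unique(np.concatenate([y_tr, y_ts])))
    col_of = {f: j for j, f in enumerate(feature_ids)}
    top = borda.top(best_count)
    missing = [f for f in top if f not in col_of]
    if missing:
        raise ValueError(f"features absent from the matrices: {missing[:5]}")
    cols = [col_of[f] for f in top]
    model = fit_classifier(config.classifier, np.asarray(X_tr)[:, cols],
                           np.asarray(y_tr), top, seed=derive_seed(seed, "final"))
    pred = model.predict(np.asarray(X_ts)[:, cols])
    return _score(np.asarray(y_ts), pred, n_classes, config.positive_class,
                  {"partition": "test", "n_features": best_count})


def develop_split(X: np.ndarray, y: np.ndarray, feature_ids: Sequence[str],
                  dev_idx: np.ndarray, test_idx: np.ndarray,
                  config: DAPConfig, rank_fn_builder, split_id: int,
                  n_classes: int) -> SplitResult:
    """One split of the DAP: CV development on `dev_idx`, one test pass.

    ``rank_fn_builder(dev_idx, split_seed, y_dev)`` returns the fold-level
    ranking function; in random-labels mode the development labels are
    permuted (seeded) before everything, including the ranking.
    """
    split_seed = derive_seed(config.seed, "dap_split", split_id)
    y_dev = np.asarray(y)[dev_idx]
    if config.random_labels:
        rng = np.random.default_rng(derive_seed(split_seed, "shuffle_labels"))
        y_dev = rng.permutation(y_dev)
    rank_fn = rank_fn_builder(dev_idx, split_seed, y_dev)
    cv = run_cv_experiment(np.asarray(X)[dev_idx], y_dev, feature_ids, config,
                           rank_fn, seed=split_seed, n_classes=n_classes)
    test = finalize_and_test(
        np.asarray(X)[dev_idx], y_dev, np.asarray(X)[test_idx],
        np.asarray(y)[test_idx], feature_ids, cv.borda, cv.best_count,
        config, seed=split_seed, n_classes=n_classes)
    return SplitResult(split_id, cv, test, cv.best_count)


def aggregate_splits(method: str, splits: Sequence[SplitResult]) -> ExperimentResult:
    """Borda-of-Bordas over the split-level lists; Nf = median best count.

    Split-level lists may rank split-local feature subsets (the compact
    intersection path); the aggregation then runs over their union.
    """
    if not splits:
        raise ValueError("no split results to aggregate")
    bob = borda_aggregate([s.cv.borda for s in splits], allow_partial=True)
    nf = float(np.median([s.best_count for s in splits]))
    return ExperimentResult(method, tuple(splits), bob, nf)


def run_dap(X: np.ndarray, y: np.ndarray, feature_ids: Sequence[str],
            labels: LabelVector, config: DAPConfig,
            rank_fn_builder=None, method: str = "juxt",
            schemes: Sequence[SplitScheme] | None = None,
            dev: str = "tr", test: str = "ts") -> ExperimentResult:
    """Full DAP over the repeated TR/TS/TS2 splits of one data view.

    By default development runs on TR and the held-out pass on TS; the
    compact-intersection path develops on TS and tests on TS2. Without a
    ``rank_fn_builder`` features are ranked by ANOVA F on fold-training
    rows.
    """
    X = np.asarray(X)
    y = np.asarray(y)
    n_classes = labels.n_classes
    if schemes is None:
        schemes = make_tr_ts_ts2_splits(labels, config.n_splits,
                                        seed=derive_seed(config.seed, "splits"))
    if rank_fn_builder is None:
        from .metrics import anova_f_rank

        def rank_fn_builder(dev_idx, split_seed, y_dev):
            X_dev = X[dev_idx]

            def rank_fn(rows):
                return anova_f_rank(X_dev[rows], y_dev[rows], feature_ids)

            return rank_fn

    results = []
    for scheme in schemes:
        dev_idx = getattr(scheme, dev)
        test_idx = getattr(scheme, test)
        results.append(develop_split(X, y, feature_ids, dev_idx, test_idx,
                                     config, rank_fn_builder, scheme.split_id,
                                     n_classes))
    return aggregate_splits(method, results)
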