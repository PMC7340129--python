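import numpy as np
import pytest

from omicsfusion.dap import (
    ClassifierSpec,
    DAPConfig,
    cv_feature_counts,
    fit_classifier,
    finalize_and_test,
    make_tr_ts_ts2_splits,
    run_cv_experiment,
    tune_lsvm_c,
)
from omicsfusion.io import LabelVector
from omicsfusion.metrics import anova_f_rank
from omicsfusion.synthetic import generate_labels


@pytest.fixture(scope="module")
def benchmark_labels() -> LabelVector:
    return generate_labels(380, (0.7, 0.3))


class TestSplits:
    def test_benchmark_sizes_and_stratification(self, benchmark_labels):
        """380 samples at 266/114 -> TR 190 (133/57), TS 114, TS2 76."""
        (s,) = make_tr_ts_ts2_splits(benchmark_labels, n_splits=1, seed=0)
        assert (len(s.tr), len(s.ts), len(s.ts2)) == (190, 114, 76)
        y = benchmark_labels.codes()
        assert np.sum(y[s.tr] == 0) == 133 and np.sum(y[s.tr] == 1) == 57

    def test_disjoint_cover_all_and_stratified_within_one(self, benchmark_labels):
        schemes = make_tr_ts_ts2_splits(benchmark_labels, n_splits=5, seed=3)
        y = benchmark_labels.codes()
        n = len(y)
        for s in schemes:
            allidx = np.concatenate([s.tr, s.ts, s.ts2])
            assert sorted(allidx.tolist()) == list(range(n))
            for part, frac in ((s.tr, 0.5), (s.ts, 0.3), (s.ts2, 0.2)):
                assert abs(len(part) - frac * n) <= 1
                for c, total in zip(*np.unique(y, return_counts=True)):
                    ideal = frac * total
                    assert abs(np.sum(y[part] == c) - ideal) <= 1

    def test_deterministic_and_distinct_across_splits(self, benchmark_labels):
        a = make_tr_ts_ts2_splits(benchmark_labels, n_splits=2, seed=9)
        b = make_tr_ts_ts2_splits(benchmark_labels, n_splits=2, seed=9)
        for x, y_ in zip(a, b):
            np.testing.assert_array_equal(x.tr, y_.tr)
        assert not np.array_equal(a[0].tr, a[1].tr)

    def test_tiny_class_error(self):
        labels = LabelVector(("a", "a", "a", "b", "b"), None)
        with pytest.raises(ValueError, match="'b'"):
            make_tr_ts_ts2_splits(labels, n_splits=1)


class TestFeatureCounts:
    @pytest.mark.parametrize("total,expected", [
        (400, (20, 40, 100, 200, 300, 400)),
        (10, (1, 3, 5, 8, 10)),
        (1, (1,)),
    ])
    def test_schedule(self, total, expected):
        assert cv_feature_counts(total) == expected

    def test_counts_ascending_and_bounded(self):
        for total in (3, 17, 123):
            counts = cv_feature_counts(total)
            assert list(counts) == sorted(set(counts))
            assert counts[-1] == total


class TestLsvmTuning:
    def test_singleton_grid(self):
        X = np.random.default_rng(0).normal(size=(20, 3))
        y = np.r_[np.zeros(10, int), np.ones(10, int)]
        spec = ClassifierSpec(kind="lsvm", c_grid=(10.0,))
        assert tune_lsvm_c(X, y, spec) == 10.0

    def test_separable_ties_return_smallest_c(self):
        rng = np.random.default_rng(1)
        X = np.r_[rng.normal(-10, 0.1, (20, 2)), rng.normal(10, 0.1, (20, 2))]
        y = np.r_[np.zeros(20, int), np.ones(20, int)]
        assert tune_lsvm_c(X, y, ClassifierSpec(kind="lsvm"), seed=0) == 0.01

    def test_chosen_c_in_grid(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 3))
        y = rng.integers(0, 2, 40)
        c = tune_lsvm_c(X, y, ClassifierSpec(kind="lsvm"), seed=1)
        assert c in (0.01, 0.1, 1.0, 10.0, 100.0, 1000.0)


class TestFitPredict:
    def test_separable_training_mcc_one(self):
        from omicsfusion.metrics import mcc_score

        rng = np.random.default_rng(3)
        X = np.r_[rng.normal(-5, 0.2, (15, 4)), rng.normal(5, 0.2, (15, 4))]
        y = np.r_[np.zeros(15, int), np.ones(15, int)]
        model = fit_classifier(ClassifierSpec(n_trees=50), X, y,
                               [f"f{i}" for i in range(4)], seed=0)
        assert mcc_score(y, model.predict(X)) == 1.0

    def test_deterministic_fit(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(40, 5))
        y = rng.integers(0, 2, 40)
        ids = [f"f{i}" for i in range(5)]
        a = fit_classifier(ClassifierSpec(n_trees=30), X, y, ids, seed=7)
        b = fit_classifier(ClassifierSpec(n_trees=30), X, y, ids, seed=7)
        np.testing.assert_array_equal(a.predict(X), b.predict(X))

    def test_prediction_aligns_columns_by_id(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(30, 4))
        y = (X[:, 0] > 0).astype(int)
        ids = ["a", "b", "c", "d"]
        model = fit_classifier(ClassifierSpec(n_trees=30), X, y, ids, seed=0)
        perm = [2, 0, 3, 1]
        permuted = model.predict(X[:, perm], feature_ids=[ids[j] for j in perm])
        np.testing.assert_array_equal(permuted, model.predict(X))

    def test_feature_mismatch_error(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(20, 2))
        y = rng.integers(0, 2, 20)
        model = fit_classifier(ClassifierSpec(n_trees=10), X, y, ["a", "b"], seed=0)
        with pytest.raises(ValueError, match="match the training features"):
            model.predict(X, feature_ids=["a", "z"])

    def test_single_class_error(self):
        with pytest.raises(ValueError, match="single class"):
            fit_classifier(ClassifierSpec(), np.zeros((4, 2)),
                           np.zeros(4, int), ["a", "b"])


def _anova_rank_fn(X, y, ids):
    def rank_fn(rows):
        return anova_f_rank(X[rows], y[rows], ids)
    return rank_fn


@pytest.fixture(scope="module")
def separable():
    rng = np.random.default_rng(8)
    n = 60
    y = np.r_[np.zeros(40, int), np.ones(20, int)]
    signal = np.where(y == 0, -3.0, 3.0)[:, None]
    X = np.c_[signal + rng.normal(0, 0.5, (n, 2)), rng.normal(size=(n, 8))]
    ids = tuple(f"f{i}" for i in range(10))
    return X, y, ids


class TestRunCV:

    def test_record_shape_and_best_count(self, separable):
        X, y, ids = separable
        config = DAPConfig(cv_repeats=2, cv_folds=3,
                           classifier=ClassifierSpec(n_trees=30), seed=0)
        res = run_cv_experiment(X, y, ids, config, _anova_rank_fn(X, y, ids))
        counts = cv_feature_counts(10)
        assert len(res.records) == 2 * 3 * len(counts)
        assert res.best_count in counts
        assert res.best_mean_mcc > 0.8
        assert res.borda.universe == frozenset(ids)

    def test_full_fraction_only_reduces_to_plain_cv(self, separable):
        X, y, ids = separable
        config = DAPConfig(cv_repeats=2, cv_folds=3, feature_fractions=(100,),
                           classifier=ClassifierSpec(n_trees=30), seed=0)
        res = run_cv_experiment(X, y, ids, config, _anova_rank_fn(X, y, ids))
        assert res.best_count == 10
        assert len(res.records) == 6

    def test_leakage_guard_poisoned_heldout_rows(self, separable):
        """A column made perfectly predictive only on held-out rows must not
        gain rank: fold ranking sees fold-training rows alone."""
        X, y, ids = separable
        config = DAPConfig(cv_repeats=2, cv_folds=3, feature_fractions=(100,),
                           classifier=ClassifierSpec(n_trees=10), seed=1)
        poison_col = 9  # pure noise in training data
        observed_ranks = []

        def spying_rank_fn(rows):
            X_poisoned = X.copy()
            heldout = np.setdiff1d(np.arange(len(y)), rows)
            X_poisoned[heldout, poison_col] = y[heldout] * 100.0
            ranked = anova_f_rank(X_poisoned[rows], y[rows], ids)
            observed_ranks.append(ranked.positions()[ids[poison_col]])
            return ranked

        run_cv_experiment(X, y, ids, config, spying_rank_fn)
        # the poison is potent: ranked on all rows it would win outright ...
        X_all_poisoned = X.copy()
        X_all_poisoned[:, poison_col] = y * 100.0
        assert anova_f_rank(X_all_poisoned, y, ids).positions()[ids[poison_col]] == 1
        # ... yet fold ranking, seeing fold-training rows only, never
        # promotes it into the informative block
        assert all(r > 2 for r in observed_ranks)

    def test_determinism(self, separable):
        X, y, ids = separable
        config = DAPConfig(cv_repeats=1, cv_folds=3,
                           classifier=ClassifierSpec(n_trees=20), seed=5)
        a = run_cv_experiment(X, y, ids, config, _anova_rank_fn(X, y, ids))
        b = run_cv_experiment(X, y, ids, config, _anova_rank_fn(X, y, ids))
        assert a == b

    def test_finalize_and_test_separable(self, separable):
        X, y, ids = separable
        config = DAPConfig(cv_repeats=1, cv_folds=3,
                           classifier=ClassifierSpec(n_trees=30), seed=0)
        res = run_cv_experiment(X, y, ids, config, _anova_rank_fn(X, y, ids))
        rec = finalize_and_test(X, y, X, y, ids, res.borda, res.best_count,
                                config, seed=0)
        assert rec.mcc == 1.0

    def test_best_count_cannot_exceed_universe(self, separable):
        X, y, ids = separable
        config = DAPConfig(cv_repeats=1, cv_folds=3,
                           classifier=ClassifierSpec(n_trees=10), seed=0)
        res = run_cv_experiment(X, y, ids, config, _anova_rank_fn(X, y, ids))
        with pytest.raises(ValueError, match="exceeds"):
            finalize_and_test(X, y, X, y, ids, res.borda, 11, config)
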