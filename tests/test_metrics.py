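import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from omicsfusion.metrics import (
    Interval,
    RankedList,
    anova_f_rank,
    binary_mcc,
    borda_aggregate,
    canberra_rank_distance,
    confusion_counts,
    mcc,
    mcc_score,
    precision_recall,
    studentized_bootstrap_ci,
)


def _rl(*ids, tag="t"):
    n = len(ids)
    return RankedList(tuple(ids), tuple(float(n - i) for i in range(n)), tag)


class TestAnovaFRank:
    def test_two_group_hand_anova(self):
        """Groups (1,2,3) vs (4,5,6): between-MS 13.5, within-MS 1 -> F=13.5."""
        from sklearn.feature_selection import f_classif

        X = np.array([[1.0], [2.0], [3.0], [4.0], [5.0], [6.0]])
        y = np.array([0, 0, 0, 1, 1, 1])
        F, _ = f_classif(X, y)
        assert F[0] == pytest.approx(13.5)
        ranked = anova_f_rank(X, y, ["f1"])
        assert ranked.scores[0] == pytest.approx(13.5)

    def test_indicator_above_constant(self):
        y = np.array([0, 0, 1, 1, 0, 1])
        X = np.c_[np.full(6, 3.0), y.astype(float)]
        ranked = anova_f_rank(X, y, ["const", "indicator"])
        assert ranked.feature_ids == ("indicator", "const")
        assert ranked.scores[0] == np.inf
        assert ranked.scores[1] == 0.0

    def test_sample_permutation_invariance(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 6))
        y = rng.integers(0, 2, 30)
        perm = rng.permutation(30)
        a = anova_f_rank(X, y)
        b = anova_f_rank(X[perm], y[perm])
        assert a.feature_ids == b.feature_ids

    def test_small_class_error(self):
        with pytest.raises(ValueError, match=">=2 samples"):
            anova_f_rank(np.zeros((3, 2)), np.array([0, 1, 1]))


class TestMCC:
    @pytest.mark.parametrize("counts,expected", [
        ((10, 10, 0, 0), 1.0),            # perfect prediction
        ((0, 0, 10, 10), -1.0),           # inverse prediction
        ((5, 5, 5, 5), 0.0),              # chance level
        ((50, 30, 10, 10), 1400.0 / 2400.0),
    ])
    def test_binary_formula(self, counts, expected):
        assert binary_mcc(*counts) == pytest.approx(expected)

    def test_zero_denominator_convention(self):
        assert binary_mcc(5, 0, 0, 5) == 0.0

    def test_equals_pearson_correlation_of_binary_vectors(self):
        """MCC is the Pearson correlation of truth/prediction indicators."""
        rng = np.random.default_rng(7)
        for _ in range(200):
            n = rng.integers(4, 40)
            yt = rng.integers(0, 2, n)
            yp = rng.integers(0, 2, n)
            got = binary_mcc(*confusion_counts(yt, yp, positive=1))
            if yt.std() == 0 or yp.std() == 0:
                assert got == 0.0
            else:
                assert got == pytest.approx(np.corrcoef(yt, yp)[0, 1], abs=1e-12)

    def test_multiclass_diagonal_is_one(self):
        assert mcc(np.diag([4, 7, 2])) == pytest.approx(1.0)

    def test_multiclass_reduces_to_binary(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            tp, tn, fp, fn = rng.integers(0, 30, 4)
            if tp + tn + fp + fn == 0:
                continue
            C = np.array([[tn, fp], [fn, tp]])
            assert mcc(C) == pytest.approx(binary_mcc(tp, tn, fp, fn), abs=1e-12)

    def test_mcc_score_matches_sklearn(self):
        from sklearn.metrics import matthews_corrcoef

        rng = np.random.default_rng(2)
        yt = rng.integers(0, 3, 60)
        yp = rng.integers(0, 3, 60)
        assert mcc_score(yt, yp) == pytest.approx(matthews_corrcoef(yt, yp))

    def test_empty_counts_error(self):
        with pytest.raises(ValueError):
            mcc(np.zeros((2, 2)))


class TestPrecisionRecall:
    def test_binary_values(self):
        C = np.array([[30, 10], [10, 50]])  # TN FP / FN TP
        prec, rec = precision_recall(C, positive=1)
        assert prec == pytest.approx(50 / 60)
        assert rec == pytest.approx(50 / 60)

    def test_no_predicted_positives(self):
        C = np.array([[20, 0], [5, 0]])
        prec, rec = precision_recall(C, positive=1)
        assert prec == 0.0
        assert rec == 0.0

    def test_macro_average_multiclass(self):
        C = np.diag([3, 4, 5])
        assert precision_recall(C) == (1.0, 1.0)


class TestBorda:
    def test_single_list_identity(self):
        rl = _rl("A", "B", "C")
        assert borda_aggregate([rl]) is rl

    def test_hand_borda_count(self):
        out = borda_aggregate([_rl("A", "B", "C"), _rl("B", "A", "C")])
        assert out.feature_ids == ("A", "B", "C")
        assert out.scores == (3.0, 3.0, 0.0)

    def test_idempotent_on_copies(self):
        rl = _rl("x", "y", "z")
        out = borda_aggregate([rl, rl, rl])
        assert out.feature_ids == rl.feature_ids

    def test_commutative(self):
        lists = [_rl("A", "B", "C", "D"), _rl("D", "C", "B", "A"),
                 _rl("B", "D", "A", "C")]
        a = borda_aggregate(lists)
        b = borda_aggregate(lists[::-1])
        assert a == b

    def test_matches_bruteforce_on_all_permutations(self):
        """Pairwise aggregation agrees with a naive positional count on
        every pair of permutations of 4 items."""
        items = ("a", "b", "c", "d")
        for p1 in itertools.permutations(items):
            for p2 in itertools.permutations(items):
                got = borda_aggregate([_rl(*p1), _rl(*p2)])
                naive = {f: (4 - p1.index(f) - 1) + (4 - p2.index(f) - 1)
                         for f in items}
                expect = sorted(items, key=lambda f: (-naive[f], f))
                assert list(got.feature_ids) == expect

    def test_universe_mismatch_error(self):
        with pytest.raises(ValueError, match="universes differ"):
            borda_aggregate([_rl("A", "B"), _rl("A", "C")])

    def test_partial_mode_unions_universes(self):
        out = borda_aggregate([_rl("A", "B"), _rl("A", "C")], allow_partial=True)
        assert out.universe == frozenset({"A", "B", "C"})
        assert out.feature_ids[0] == "A"


class TestCanberra:
    def test_identity_and_reversal(self):
        a = _rl("A", "B", "C")
        assert canberra_rank_distance(a, a) == 0.0
        assert canberra_rank_distance(a, _rl("C", "B", "A")) == pytest.approx(1.0)

    def test_symmetric(self):
        a, b = _rl("A", "B", "C", "D"), _rl("B", "D", "A", "C")
        assert canberra_rank_distance(a, b) == pytest.approx(
            canberra_rank_distance(b, a))

    def test_matches_bruteforce_on_permutations(self):
        items = ("a", "b", "c", "d", "e")
        perms = list(itertools.permutations(items))[:40]
        for p1 in perms:
            for p2 in perms[:10]:
                got = canberra_rank_distance(_rl(*p1), _rl(*p2))
                brute = sum(
                    abs((p1.index(f) + 1) - (p2.index(f) + 1))
                    / ((p1.index(f) + 1) + (p2.index(f) + 1))
                    for f in items)
                assert got == pytest.approx(brute)

    def test_identity_of_indiscernibles(self):
        a, b = _rl("A", "B", "C"), _rl("A", "C", "B")
        assert canberra_rank_distance(a, b) > 0


class TestStudentizedBootstrap:
    def test_degenerate_all_equal(self):
        iv = studentized_bootstrap_ci([3.0] * 5)
        assert (iv.lower, iv.upper) == (3.0, 3.0)

    def test_contains_mean_for_symmetric_data(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 12)
        iv = studentized_bootstrap_ci(x, seed=1)
        assert iv.lower <= x.mean() <= iv.upper

    def test_deterministic_given_seed(self):
        x = np.arange(10.0)
        a = studentized_bootstrap_ci(x, seed=5)
        b = studentized_bootstrap_ci(x, seed=5)
        assert (a.lower, a.upper) == (b.lower, b.upper)

    def test_too_few_values_error(self):
        with pytest.raises(ValueError):
            studentized_bootstrap_ci([1.0, 2.0])

    def test_coverage_on_standard_normal(self):
        """Monte-Carlo coverage of the 95% bootstrap-t interval on
        Normal(0,1) samples of size 10 lies in (0.90, 0.99)."""
        rng = np.random.default_rng(123)
        hits = 0
        n_rep = 1000
        for r in range(n_rep):
            x = rng.normal(0, 1, 10)
            iv = studentized_bootstrap_ci(x, B=1000, inner=100, seed=r)
            hits += 0.0 in iv
        coverage = hits / n_rep
        assert 0.90 < coverage < 0.99


class TestRankedListInvariants:
    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 1000), min_size=1, max_size=20, unique=True))
    def test_sorted_scores_accepted_any_permutation_rejected_if_increasing(self, xs):
        scores = sorted((float(x) for x in xs), reverse=True)
        ids = tuple(f"f{i}" for i in range(len(xs)))
        rl = RankedList(ids, tuple(scores), "t")
        assert rl.positions()[ids[0]] == 1

    def test_increasing_scores_rejected(self):
        with pytest.raises(ValueError, match="non-increasing"):
            RankedList(("a", "b"), (1.0, 2.0), "t")

    def test_interval_ordering_enforced(self):
        with pytest.raises(ValueError):
            Interval(2.0, 1.0)
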