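"""t / rank-sum filter statistics, fold aggregation and top-n selection."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from hidimsel import (
    combine_tt_wrs,
    kfold_filter_weights,
    select_top,
    welch_t,
    wrs_score,
)
from hidimsel.filters import GeneScoreTable

from conftest import toy_dataset

floats_vec = st.lists(
    st.floats(-50, 50, allow_nan=False), min_size=2, max_size=8
)


class TestWelchT:
    def test_identical_samples(self):
        r = welch_t([1, 2, 3], [1, 2, 3])
        assert r.t == 0.0

    def test_derived_value(self):
        r = welch_t([1, 2, 3], [4, 5, 6])
        assert r.t == pytest.approx(-3 / math.sqrt(2 / 3), abs=1e-12)

    def test_antisymmetry(self):
        a, b = [1.0, 4.0, 2.0], [3.0, 8.0, 5.0, 9.0]
        assert welch_t(a, b).t == pytest.approx(-welch_t(b, a).t)
        assert welch_t(a, b).score == welch_t(b, a).score

    def test_zero_variance_cases(self):
        assert welch_t([2, 2], [2, 2]).t == 0.0
        with pytest.warns(UserWarning):
            r = welch_t([3, 3], [1, 1])
        assert r.t == math.inf and r.p == 0.0

    @given(floats_vec, floats_vec)
    @settings(max_examples=60, deadline=None)
    def test_matches_scipy(self, x, y):
        r = welch_t(x, y)
        if np.var(x, ddof=1) + np.var(y, ddof=1) == 0:
            return
        ref = stats.ttest_ind(x, y, equal_var=False)
        assert r.t == pytest.approx(ref.statistic, rel=1e-9, abs=1e-9)
        assert r.p == pytest.approx(ref.pvalue, rel=1e-9, abs=1e-12)

    def test_affine_invariance_of_score(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(0, 1, 6), rng.normal(1, 2, 9)
        s0 = welch_t(x, y).score
        assert welch_t(3.7 * x + 11, 3.7 * y + 11).score == pytest.approx(s0)


class TestWrs:
    def test_complete_separation(self):
        r = wrs_score([1, 2, 3], [4, 5, 6, 7])
        assert r.s == 0 and r.q == 12

    def test_tie_counts(self):
        r = wrs_score([1], [1])
        assert r.s == 1 and r.q == 1

    def test_enumerated_pairs(self):
        r = wrs_score([1, 3], [2, 4])
        assert r.s == 1 and r.q == 3

    @given(floats_vec, floats_vec)
    @settings(max_examples=80, deadline=None)
    def test_matches_pair_enumeration(self, x0, x1):
        r = wrs_score(x0, x1)
        s = sum(1 for a in x0 for b in x1 if b - a <= 0)
        assert r.s == s
        assert r.q == max(s, len(x0) * len(x1) - s)
        # importance bounds and class-swap invariance
        assert math.ceil(len(x0) * len(x1) / 2) <= r.q <= len(x0) * len(x1)

    def test_class_swap_invariance_without_ties(self):
        rng = np.random.default_rng(9)
        x0, x1 = rng.normal(size=5), rng.normal(size=7)
        a, b = wrs_score(x0, x1), wrs_score(x1, x0)
        assert a.s + b.s == 35
        assert a.q == b.q


def brute_force_weights(ds, filter_name, K, seed):
    """Independent fold-rank summation using pandas ranks and scipy stats."""
    import pandas as pd

    skf = StratifiedKFold(n_splits=K, shuffle=True, random_state=seed)
    total = np.zeros(ds.n_genes)
    for train, _ in skf.split(ds.values.T, ds.labels):
        scores = []
        for i in range(ds.n_genes):
            x = ds.values[i, train][ds.labels[train] == 0]
            y = ds.values[i, train][ds.labels[train] == 1]
            if filter_name == "tt":
                scores.append(abs(stats.ttest_ind(x, y, equal_var=False).statistic))
            else:
                s = sum(1 for a in x for b in y if b - a <= 0)
                scores.append(max(s, len(x) * len(y) - s))
        ranks = pd.Series(scores).rank(ascending=False, method="average")
        total += ds.n_genes - ranks.to_numpy() + 1
    return total


class TestKfoldWeights:
    @pytest.mark.parametrize("filter_name", ["tt", "wrs"])
    def test_matches_brute_force(self, filter_name):
        ds = toy_dataset(n_genes=30, n_per_class=12, n_informative=4, seed=2)
        table = kfold_filter_weights(ds, filter_name, K=5, seed=21)
        expected = brute_force_weights(ds, filter_name, K=5, seed=21)
        np.testing.assert_allclose(table.weights, expected)

    def test_k1_single_fold_weight(self):
        ds = toy_dataset(n_genes=12, n_per_class=8, seed=4)
        table = kfold_filter_weights(ds, "tt", K=1, seed=0)
        assert table.fold_weights.shape == (12, 1)
        np.testing.assert_allclose(table.weights, table.fold_weights[:, 0])
        # ranking equals plain single-pass filter ranking on the full data
        scores = [
            welch_t(
                ds.values[i, ds.labels == 0], ds.values[i, ds.labels == 1]
            ).score
            for i in range(ds.n_genes)
        ]
        plain = sorted(range(12), key=lambda i: (-scores[i], ds.gene_ids[i]))
        assert [ds.gene_ids[i] for i in plain] == table.ordered_gene_ids()

    def test_planted_gene_ranks_first(self):
        ds = toy_dataset(n_genes=100, n_per_class=15, n_informative=1, effect=6, seed=8)
        table = kfold_filter_weights(ds, "tt", K=10, seed=3)
        assert table.ordered_gene_ids()[0] == "g1"

    def test_gene_equivariance(self):
        ds = toy_dataset(n_genes=20, n_per_class=10, seed=6)
        perm = np.random.default_rng(1).permutation(20)
        permuted = type(ds)(
            [ds.gene_ids[i] for i in perm],
            ds.sample_ids,
            ds.values[perm, :],
            ds.labels,
            ds.class_names,
        )
        t1 = kfold_filter_weights(ds, "wrs", K=5, seed=9)
        t2 = kfold_filter_weights(permuted, "wrs", K=5, seed=9)
        w1 = dict(zip(t1.gene_ids, t1.weights))
        w2 = dict(zip(t2.gene_ids, t2.weights))
        assert w1 == w2

    def test_ranks_are_permutation(self, small_ds):
        table = kfold_filter_weights(small_ds, "tt", K=5, seed=0)
        assert sorted(table.ranks) == list(range(1, small_ds.n_genes + 1))

    def test_fold_reduction_warning(self):
        ds = toy_dataset(n_genes=5, n_per_class=4, seed=0)
        with pytest.warns(UserWarning, match="reducing folds"):
            kfold_filter_weights(ds, "tt", K=10, seed=0)


def make_table(ids, weights):
    w = np.asarray(weights, dtype=float)
    order = sorted(range(len(ids)), key=lambda i: (-w[i], ids[i]))
    ranks = np.empty(len(ids), dtype=int)
    for pos, i in enumerate(order):
        ranks[i] = pos + 1
    return GeneScoreTable(list(ids), w[:, None], w, ranks)


class TestCombine:
    def test_idempotence_of_identical_rankings(self):
        a = make_table(["g1", "g2", "g3"], [9, 5, 1])
        b = make_table(["g1", "g2", "g3"], [90, 50, 10])
        c = combine_tt_wrs(a, b)
        assert c.ordered_gene_ids() == ["g1", "g2", "g3"]

    def test_constant_table_is_neutral(self):
        a = make_table(["g1", "g2", "g3"], [4, 4, 4])
        b = make_table(["g1", "g2", "g3"], [1, 7, 3])
        c = combine_tt_wrs(a, b)
        assert c.ordered_gene_ids() == b.ordered_gene_ids()

    def test_hand_computed_five_genes(self):
        ids = ["g1", "g2", "g3", "g4", "g5"]
        a = make_table(ids, [10, 8, 6, 4, 2])   # normalized: 1, .75, .5, .25, 0
        b = make_table(ids, [1, 5, 3, 2, 4])    # normalized: 0, 1, .5, .25, .75
        c = combine_tt_wrs(a, b)
        np.testing.assert_allclose(c.weights, [0.5, 0.875, 0.5, 0.25, 0.375])
        # g1/g3 tie at 0.5 broken by gene id
        assert c.ordered_gene_ids() == ["g2", "g1", "g3", "g5", "g4"]

    def test_mismatched_universe(self):
        with pytest.raises(ValueError):
            combine_tt_wrs(make_table(["a"], [1]), make_table(["b"], [1]))


class TestSelectTop:
    def test_identity_when_n_equals_g(self, small_ds):
        table = kfold_filter_weights(small_ds, "tt", K=5, seed=0)
        assert select_top(table, small_ds, small_ds.n_genes).gene_ids == small_ds.gene_ids

    def test_cap_with_warning(self, small_ds):
        table = kfold_filter_weights(small_ds, "tt", K=5, seed=0)
        with pytest.warns(UserWarning, match="keeping all"):
            out = select_top(table, small_ds, 200)
        assert out.n_genes == small_ds.n_genes

    def test_top3_of_hand_set_table(self):
        ids = ["g1", "g2", "g3", "g4", "g5"]
        ds = toy_dataset(n_genes=5, n_per_class=5)
        table = make_table(ids, [1, 9, 5, 7, 3])
        out = select_top(table, ds, 3)
        assert set(out.gene_ids) == {"g2", "g4", "g3"}
        # dataset gene order preserved among the selected
        assert out.gene_ids == ["g2", "g3", "g4"]
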