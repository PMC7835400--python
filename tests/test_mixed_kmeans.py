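"""Weighted k-means: dummy expansion, Lloyd fit, cluster-count selection."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from germcore import (
    PhenotypeTable,
    TraitSchema,
    TraitSpec,
    cluster_single_trait,
    expand_dummies,
    fit,
    select_k,
)
from germcore.mixed_kmeans import ExpandedMatrix

from conftest import make_clustered_table


def _table(quant=None, qual=None, levels=("A", "B", "C")):
    traits, data = [], {}
    if quant is not None:
        traits.append(TraitSpec("q", "quantitative"))
        data["q"] = quant
    if qual is not None:
        traits.append(TraitSpec("c", "qualitative", levels=levels))
        data["c"] = qual
    n = len(next(iter(data.values())))
    frame = pd.DataFrame(data, index=[f"a{i}" for i in range(n)])
    return PhenotypeTable(frame, TraitSchema(tuple(traits)))


class TestExpandDummies:
    def test_indicator_columns_per_level(self):
        table = _table(qual=["A", "B"])
        mat = expand_dummies(table, w=0.5)
        assert mat.coordinates.shape == (2, 2)
        np.testing.assert_array_equal(mat.coordinates, [[1, 0], [0, 1]])
        assert [lv for _, lv in mat.column_map] == ["A", "B"]

    def test_weights_by_trait_kind(self):
        table = _table(quant=[1.0, 2.0], qual=["A", "B"])
        mat = expand_dummies(table, w=0.7)
        kinds = [lv is None for _, lv in mat.column_map]
        for is_quant, w in zip(kinds, mat.column_weights):
            assert w == pytest.approx(0.3 if is_quant else 0.7)

    def test_qualitative_block_sums_to_one(self, clustered_table):
        table, _ = clustered_table
        mat = expand_dummies(table)
        qual_cols = [i for i, (_, lv) in enumerate(mat.column_map) if lv is not None]
        per_trait = {}
        for i in qual_cols:
            per_trait.setdefault(mat.column_map[i][0], []).append(i)
        for cols in per_trait.values():
            np.testing.assert_allclose(mat.coordinates[:, cols].sum(axis=1), 1.0)

    def test_constant_quantitative_becomes_zero_column(self):
        table = _table(quant=[3.0, 3.0, 3.0])
        mat = expand_dummies(table)
        np.testing.assert_array_equal(mat.coordinates, np.zeros((3, 1)))

    def test_missing_cell_rejected(self, small_table):
        with pytest.raises(ValueError, match="missing"):
            expand_dummies(small_table)


def _exhaustive_objective(X, k):
    best = np.inf
    for labels in itertools.product(range(k), repeat=len(X)):
        labels = np.array(labels)
        if len(set(labels.tolist())) < k:
            continue
        obj = sum(
            ((X[labels == l] - X[labels == l].mean(axis=0)) ** 2).sum()
            for l in range(k)
        )
        best = min(best, obj)
    return best


class TestFit:
    def test_points_at_k_locations_reach_zero(self):
        X = np.repeat(np.array([[0.0], [5.0], [9.0]]), 3, axis=0)
        mat = ExpandedMatrix(X, np.ones(1), [("q", None)], [f"a{i}" for i in range(9)])
        model = fit(mat, 3, n_init=10, seed=0)
        assert model.objective == pytest.approx(0.0)
        assert model.variance_explained == pytest.approx(1.0)

    def test_two_triads_split_matches_brute_force(self):
        X = np.array([[0.0, 0], [0.1, 0], [0, 0.1], [5, 5], [5.1, 5], [5, 5.1]])
        mat = ExpandedMatrix(X, np.ones(2), [("a", None), ("b", None)],
                             [f"p{i}" for i in range(6)])
        model = fit(mat, 2, n_init=10, seed=0)
        assert len(set(model.labels[:3])) == 1 and len(set(model.labels[3:])) == 1
        assert model.objective == pytest.approx(_exhaustive_objective(X, 2))

    @pytest.mark.parametrize("trial", range(6))
    def test_matches_exhaustive_partition_optimum(self, trial):
        rng = np.random.default_rng(trial)
        n, k = int(rng.integers(5, 9)), int(rng.integers(2, 4))
        X = rng.normal(size=(n, 2))
        mat = ExpandedMatrix(X, np.ones(2), [("a", None), ("b", None)],
                             [f"p{i}" for i in range(n)])
        model = fit(mat, k, n_init=20, seed=trial)
        assert model.objective == pytest.approx(_exhaustive_objective(X, k))

    def test_agrees_with_sklearn_on_weighted_coordinates(self, clustered_table):
        table, _ = clustered_table
        mat = expand_dummies(table)
        model = fit(mat, 3, n_init=10, seed=0)
        sk = KMeans(3, n_init=10, random_state=0).fit(mat.scaled)
        assert model.objective == pytest.approx(sk.inertia_, rel=1e-6)
        assert adjusted_rand_score(model.labels, sk.labels_) == pytest.approx(1.0)

    def test_recovers_planted_clusters(self, clustered_table):
        table, truth = clustered_table
        mat = expand_dummies(table)
        model = fit(mat, 3, n_init=10, seed=0)
        true = [truth.cluster_labels[a] for a in table.accession_ids]
        assert adjusted_rand_score(true, model.labels) > 0.95

    def test_weight_extremes_change_which_traits_matter(self):
        # w -> 1: only qualitative columns matter (perturbing quantitative
        # values leaves the fit unchanged); w -> 0: the reverse
        rng = np.random.default_rng(0)
        quant = rng.normal(size=20).round(3).tolist()
        qual = ["A"] * 10 + ["B"] * 10
        table = _table(quant=quant, qual=qual, levels=("A", "B"))
        perturbed_quant = _table(
            quant=rng.normal(size=20).round(3).tolist(), qual=qual,
            levels=("A", "B"),
        )
        perturbed_qual = _table(
            quant=quant, qual=[qual[i] for i in rng.permutation(20)],
            levels=("A", "B"),
        )
        hi = fit(expand_dummies(table, w=0.999), 2, n_init=10, seed=0)
        assert len(set(hi.labels[:10])) == 1 and len(set(hi.labels[10:])) == 1
        hi2 = fit(expand_dummies(perturbed_quant, w=0.999), 2, n_init=10, seed=0)
        assert adjusted_rand_score(hi.labels, hi2.labels) == pytest.approx(1.0)
        lo = fit(expand_dummies(table, w=0.001), 2, n_init=10, seed=0)
        lo2 = fit(expand_dummies(perturbed_qual, w=0.001), 2, n_init=10, seed=0)
        assert adjusted_rand_score(lo.labels, lo2.labels) == pytest.approx(1.0)
        # the low-w split is contiguous in the quantitative ordering
        ordered = lo.labels[np.argsort(quant)]
        assert (np.diff(ordered) != 0).sum() == 1

    def test_objective_not_worse_than_initialization(self, clustered_table):
        table, _ = clustered_table
        mat = expand_dummies(table)
        scaled = mat.scaled
        model = fit(mat, 4, n_init=1, seed=1)
        # random assignment objective as an upper bound witness
        rng = np.random.default_rng(0)
        labels = rng.integers(4, size=len(scaled))
        rand_obj = sum(
            ((scaled[labels == l] - scaled[labels == l].mean(axis=0)) ** 2).sum()
            for l in range(4)
        )
        assert model.objective <= rand_obj

    def test_invalid_k_rejected(self, clustered_table):
        table, _ = clustered_table
        mat = expand_dummies(table)
        with pytest.raises(ValueError):
            fit(mat, 0)
        with pytest.raises(ValueError):
            fit(mat, len(mat.ids) + 1)


class TestSelectK:
    def test_forced_single_candidate(self, clustered_table):
        table, _ = clustered_table
        k, model = select_k(table, k_range=[2], n_init=5, seed=0)
        assert k == 2 and model.criteria_met is False

    def test_empty_range_rejected(self, clustered_table):
        table, _ = clustered_table
        with pytest.raises(ValueError):
            select_k(table, k_range=[])

    def test_criteria_table_tracks_thresholds(self):
        table, _ = make_clustered_table(seed=3, n=120, k=4, separation=8.0)
        k, model = select_k(table, k_range=range(2, 10), n_init=5, seed=0)
        tab = model.criteria_table
        assert set(tab.columns) >= {"k", "shannon", "nei", "variance_explained"}
        if model.criteria_met:
            row = tab[tab["k"] == k].iloc[0]
            assert row["shannon"] >= 0.90
            assert row["nei"] >= 0.85
            assert row["variance_explained"] >= 0.70


class TestSingleTrait:
    def test_two_value_split(self):
        table = _table(quant=[1.0, 1.0, 1.0, 10.0, 10.0, 10.0])
        model = cluster_single_trait(table, "q", k_range=[2], n_init=5)
        assert model.k == 2
        assert len(set(model.labels[:3])) == 1 and len(set(model.labels[3:])) == 1
        assert model.objective == pytest.approx(0.0)

    def test_matches_dynamic_programming_partition(self):
        # exhaustive optimal contiguous 1-D partition as oracle
        values = np.arange(12, dtype=float)
        table = _table(quant=values.tolist())
        model = cluster_single_trait(table, "q", k_range=[3], n_init=20)

        z = (values - values.mean()) / values.std()

        def best_partition(xs, k):
            n = len(xs)
            cost = {}
            for i in range(n):
                for j in range(i, n):
                    seg = xs[i:j + 1]
                    cost[i, j] = ((seg - seg.mean()) ** 2).sum()
            dp = [[np.inf] * (k + 1) for _ in range(n + 1)]
            dp[0][0] = 0.0
            for end in range(1, n + 1):
                for parts in range(1, k + 1):
                    for start in range(end):
                        dp[end][parts] = min(
                            dp[end][parts],
                            dp[start][parts - 1] + cost[start, end - 1],
                        )
            return dp[n][k]

        assert model.objective == pytest.approx(best_partition(np.sort(z), 3))

    def test_single_distinct_value_degenerate(self):
        table = _table(quant=[4.0] * 6)
        model = cluster_single_trait(table, "q")
        assert model.k == 1 and model.variance_explained == 1.0

    def test_assign_maps_new_values_to_nearest_cluster(self):
        table = _table(quant=[1.0, 1.0, 10.0, 10.0])
        model = cluster_single_trait(table, "q", k_range=[2], n_init=5)
        other = _table(quant=[0.5, 11.0])
        assign = model.assign(other, "q")
        full = model.assign(table, "q")
        assert assign[0] == full[0] and assign[1] == full[-1]

    def test_qualitative_trait_rejected(self):
        table = _table(qual=["A", "B"])
        with pytest.raises(ValueError, match="qualitative"):
            cluster_single_trait(table, "c")
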