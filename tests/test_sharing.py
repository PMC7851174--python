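import numpy as np
import pandas as pd
import pytest

from sqtlmap.sharing import (
    bakers_gamma,
    centroid_distance,
    cluster_and_compare,
    cluster_tissues,
    jaccard_sharing,
    pairwise_sharing,
    sharing_corr,
    tau_expression,
    tau_index,
    tau_splicing,
    tissue_specificity,
    to_newick,
    percentile_filter,
)
from sqtlmap.simulate import SimulationSpec, simulate_multitissue_results


def _tissue(mds, sig=None):
    n = len(mds)
    return pd.DataFrame({
        "variant_id": [f"v{i}" for i in range(n)],
        "gene_id": [f"g{i}" for i in range(n)],
        "md": mds,
        "fdr_q": [0.01] * n,
        "significant": sig if sig is not None else [True] * n,
    })


class TestSharingCorr:
    def test_identical_md_vectors_give_one(self):
        t = _tissue([0.1, 0.2, 0.3, 0.4])
        assert sharing_corr(t, t) == pytest.approx(1.0)

    def test_reversed_linear_values_give_minus_one(self):
        t1 = _tissue([0.1, 0.2, 0.3, 0.4])
        t2 = _tissue([0.4, 0.3, 0.2, 0.1])
        assert sharing_corr(t1, t2) == pytest.approx(-1.0)

    def test_empty_intersection_is_nan_with_warning(self):
        t1 = _tissue([0.1, 0.2, 0.3])
        t2 = _tissue([0.1, 0.2, 0.3])
        t2["variant_id"] = ["x1", "x2", "x3"]
        with pytest.warns(UserWarning):
            assert np.isnan(sharing_corr(t1, t2))

    def test_synthetic_sharing_fixture_recovered(self):
        spec = SimulationSpec(seed=11)
        t1, t2 = simulate_multitissue_results(spec, 2, sharing=0.8, n_pairs=10_000)
        r = sharing_corr(t1, t2)
        assert r == pytest.approx(0.8, abs=0.05)


class TestJaccard:
    def test_identical_sets_give_one(self):
        t = _tissue([0.1, 0.2])
        assert jaccard_sharing(t, t) == 1.0

    def test_disjoint_sets_give_zero(self):
        t1 = _tissue([0.1, 0.2], sig=[True, False])
        t2 = _tissue([0.1, 0.2], sig=[False, True])
        assert jaccard_sharing(t1, t2) == 0.0

    def test_definition_on_quarter_overlap(self):
        t1 = _tissue([0.1] * 4, sig=[True, True, False, False])
        t2 = _tissue([0.1] * 4, sig=[True, False, True, True])
        # intersection {v0}, union {v0,v1,v2,v3}
        assert jaccard_sharing(t1, t2) == pytest.approx(0.25)

    def test_empty_union_is_zero_by_convention(self):
        t = _tissue([0.1], sig=[False])
        assert jaccard_sharing(t, t) == 0.0


class TestSpecificity:
    def test_full_similarity_gives_zero_specificity(self):
        m = pd.DataFrame(np.ones((3, 3)), index=list("abc"), columns=list("abc"))
        assert (tissue_specificity(m) == 0.0).all()

    def test_orthogonal_tissue_has_specificity_one(self):
        m = pd.DataFrame(np.ones((3, 3)), index=list("abc"), columns=list("abc"))
        m.loc["a", ["b", "c"]] = 0.0
        m.loc[["b", "c"], "a"] = 0.0
        s = tissue_specificity(m)
        assert s["a"] == pytest.approx(1.0)
        assert s["b"] == pytest.approx(0.5)

    def test_three_tissue_hand_means(self):
        m = pd.DataFrame(np.eye(3), index=list("abc"), columns=list("abc"))
        m.loc["a", "b"] = m.loc["b", "a"] = 0.8
        m.loc["a", "c"] = m.loc["c", "a"] = 0.6
        m.loc["b", "c"] = m.loc["c", "b"] = 0.4
        s = tissue_specificity(m)
        assert s["a"] == pytest.approx(1 - 0.7)
        assert s["b"] == pytest.approx(1 - 0.6)
        assert s["c"] == pytest.approx(1 - 0.5)

    def test_single_tissue_rejected(self):
        with pytest.raises(ValueError):
            tissue_specificity(pd.DataFrame([[1.0]], index=["a"], columns=["a"]))


class TestCentroidDistance:
    def _sets(self, rng, n_pairs=5, dim=3):
        c1, c2 = {}, {}
        for j in range(n_pairs):
            c1[f"p{j}"] = {k: rng.normal(size=dim) for k in range(3)}
            c2[f"p{j}"] = {k: rng.normal(size=dim) for k in range(3)}
        return c1, c2

    def test_identical_sets_give_zero(self, rng):
        c1, _ = self._sets(rng)
        assert centroid_distance(c1, c1) == 0.0

    def test_unit_shift_per_group_gives_three(self):
        c1 = {"p": {k: np.array([0.0, 0.0]) for k in range(3)}}
        c2 = {"p": {k: np.array([1.0, 0.0]) for k in range(3)}}
        assert centroid_distance(c1, c2) == pytest.approx(3.0)

    def test_equals_naive_double_loop(self, rng):
        c1, c2 = self._sets(rng)
        total = 0.0
        for pair in c1:  # independently coded evaluation of the definition
            for k in c1[pair]:
                total += np.sqrt(((c1[pair][k] - c2[pair][k]) ** 2).sum())
        assert centroid_distance(c1, c2) == pytest.approx(total / len(c1))

    def test_symmetry(self, rng):
        c1, c2 = self._sets(rng)
        assert centroid_distance(c1, c2) == pytest.approx(centroid_distance(c2, c1))

    def test_mismatched_pair_universe_rejected(self, rng):
        c1, c2 = self._sets(rng)
        del c2["p0"]
        with pytest.raises(ValueError):
            centroid_distance(c1, c2)

    def test_group_absent_in_one_tissue_drops_pair(self, rng):
        c1, c2 = self._sets(rng, n_pairs=2)
        del c2["p0"][2]
        d_all = centroid_distance({"p1": c1["p1"]}, {"p1": c2["p1"]})
        assert centroid_distance(c1, c2) == pytest.approx(d_all)


class TestClustering:
    def _distance(self, rng, n=10):
        m = rng.uniform(0.1, 1.0, size=(n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0.0)
        labels = [f"t{i}" for i in range(n)]
        return pd.DataFrame(m, index=labels, columns=labels)

    def test_tree_vs_itself_gives_gamma_one(self, rng):
        d = self._distance(rng)
        out = cluster_and_compare(d, d, n_shuffles=200, seed=0)
        assert out["gamma"] == pytest.approx(1.0)
        assert out["p_value"] < 0.05

    def test_gamma_symmetric_in_arguments(self, rng):
        d1, d2 = self._distance(rng), self._distance(rng)
        l1 = cluster_tissues(d1)
        l2 = cluster_tissues(d2)
        assert bakers_gamma(l1, l2, 10) == pytest.approx(bakers_gamma(l2, l1, 10))

    def test_independent_trees_center_near_zero(self, rng):
        gammas = []
        for _ in range(20):
            d1, d2 = self._distance(rng), self._distance(rng)
            gammas.append(bakers_gamma(cluster_tissues(d1), cluster_tissues(d2), 10))
        assert abs(np.mean(gammas)) < 0.25

    def test_leaf_mismatch_rejected(self, rng):
        d1 = self._distance(rng)
        d2 = self._distance(rng)
        d2.index = d2.columns = [f"x{i}" for i in range(10)]
        with pytest.raises(ValueError):
            cluster_and_compare(d1, d2)

    def test_too_few_leaves_rejected(self, rng):
        d = self._distance(rng, n=3)
        with pytest.raises(ValueError):
            cluster_and_compare(d, d)

    def test_newick_export_parses_with_all_leaves(self, rng):
        import dendropy

        d = self._distance(rng, n=6)
        link = cluster_tissues(d)
        nwk = to_newick(link, list(d.index))
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        taxa = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
        assert taxa == set(d.index)


class TestTau:
    def test_uniform_profile_gives_zero(self):
        assert tau_index([2.0, 2.0, 2.0]) == 0.0

    def test_one_hot_profile_gives_one(self):
        assert tau_index([0.0, 0.0, 5.0]) == 1.0

    def test_two_tissue_worked_value(self):
        assert tau_index([1.0, 0.5]) == pytest.approx(0.5)

    def test_monotone_in_dominance(self, rng):
        x = rng.uniform(0.1, 1.0, size=6)
        base = tau_index(x)
        x2 = x.copy()
        x2[np.argmax(x2)] *= 2
        assert tau_index(x2) >= base

    def test_bounds_on_random_profiles(self, rng):
        for _ in range(50):
            x = rng.uniform(0, 1, size=rng.integers(2, 8))
            if x.max() == 0:
                continue
            assert 0.0 <= tau_index(x) <= 1.0

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            tau_index([0.0, 0.0])

    def test_tau_splicing_caps_underflowed_fdr(self):
        v = tau_splicing([1e-320, 0.5])  # -log10 underflows to inf without cap
        assert 0.0 <= v <= 1.0
        assert tau_expression([3.0, 3.0]) == 0.0

    def test_percentile_filter_selects_extremes(self):
        s = pd.Series(np.arange(10, dtype=float), index=list("abcdefghij"))
        top = percentile_filter(s, 20, top=True)
        bottom = percentile_filter(s, 20, top=False)
        assert "j" in top and "a" in bottom
        assert len(top) <= 3 and len(bottom) <= 3


class TestPairwiseMatrix:
    def test_matrix_is_symmetric_with_unit_diagonal(self):
        spec = SimulationSpec(seed=2)
        tissues = dict(zip("abc", simulate_multitissue_results(spec, 3, sharing=0.6,
                                                               n_pairs=2000)))
        m = pairwise_sharing(tissues, metric="md")
        np.testing.assert_allclose(m.to_numpy(), m.to_numpy().T)
        np.testing.assert_allclose(np.diag(m.to_numpy()), 1.0)


class TestCentroidSetConstruction:
    def test_centroids_from_adjusted_phenotype(self, rng):
        from sqtlmap.sharing import centroid_set

        Y = rng.normal(size=(30, 3))
        dose = np.repeat([0, 1, 2], 10)
        cs = centroid_set(Y, dose)
        assert set(cs) == {0, 1, 2}
        np.testing.assert_allclose(cs[1], Y[10:20].mean(axis=0))
        # absent dosage groups are simply missing
        cs2 = centroid_set(Y[:20], dose[:20])
        assert set(cs2) == {0, 1}
        # distance between a tissue and itself is zero
        from sqtlmap.sharing import centroid_distance

        assert centroid_distance({"p": cs}, {"p": cs}) == 0.0
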