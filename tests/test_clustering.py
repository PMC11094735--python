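import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from nanofp.clustering import (
    DistanceMatrix,
    cut_tree,
    elbow_curve,
    kmeans_partition,
    molecule_distance_matrix,
    pca_variance,
    select_representatives,
    ward_linkage,
    ward_linkage_molecules,
)
from nanofp.matrix_io import FreeEnergyMatrix
from oracles import ward_oracle


def matrix_from(values, mol_prefix="m", mat_prefix="s"):
    values = np.asarray(values, dtype=float)
    return FreeEnergyMatrix(
        molecule_ids=[f"{mol_prefix}{i}" for i in range(values.shape[0])],
        material_ids=[f"{mat_prefix}{j}" for j in range(values.shape[1])],
        values=values,
    )


class TestDistanceMatrix:
    def test_identical_rows_have_zero_distance(self):
        m = matrix_from([[1.0, 2.0], [1.0, 2.0], [0.0, 0.0]])
        d = molecule_distance_matrix(m)
        assert d.d[0, 1] == 0.0

    def test_three_four_five_triangle(self):
        m = matrix_from([[0.0, 0.0], [3.0, 4.0]])
        assert molecule_distance_matrix(m).d[0, 1] == pytest.approx(5.0)
        assert molecule_distance_matrix(m, rms=True).d[0, 1] == pytest.approx(
            5.0 / np.sqrt(2)
        )

    def test_agrees_with_brute_force_double_loop(self, rng):
        X = rng.normal(size=(6, 5))
        d = molecule_distance_matrix(matrix_from(X)).d
        for i in range(6):
            for j in range(6):
                assert d[i, j] == pytest.approx(np.sqrt(np.sum((X[i] - X[j]) ** 2)))

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(ids=["a", "b"], d=np.array([[0.0, 1.0], [2.0, 0.0]]))


class TestWardLinkage:
    def test_two_points_single_merge_at_their_distance(self):
        m = matrix_from([[0.0, 0.0], [3.0, 4.0]])
        t = ward_linkage_molecules(m)
        assert t.Z.shape == (1, 4)
        assert t.Z[0, 2] == pytest.approx(5.0)

    def test_far_pairs_merge_before_cross_merge(self):
        m = matrix_from([[0.0, 0.0], [0.1, 0.0], [50.0, 0.0], [50.1, 0.0]])
        merges = ward_linkage_molecules(m).merges_as_leaf_sets()
        assert merges[0] in (frozenset({0, 1}), frozenset({2, 3}))
        assert merges[1] in (frozenset({0, 1}), frozenset({2, 3}))
        assert merges[-1] == frozenset({0, 1, 2, 3})

    def test_matches_exhaustive_oracle_on_random_instances(self, rng):
        for _ in range(25):
            n = int(rng.integers(3, 9))
            X = rng.normal(size=(n, 3))
            t = ward_linkage_molecules(matrix_from(X))
            expected = ward_oracle(X)
            got = list(zip(t.merges_as_leaf_sets(), t.merge_heights()))
            assert [m for m, _ in got] == [m for m, _ in expected]
            assert np.allclose([h for _, h in got], [h for _, h in expected])

    def test_heights_monotone_non_decreasing(self, rng):
        X = rng.normal(size=(15, 4))
        h = ward_linkage_molecules(matrix_from(X)).merge_heights()
        assert np.all(np.diff(h) >= -1e-12)

    def test_single_item_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            ward_linkage(DistanceMatrix(ids=["a"], d=np.zeros((1, 1))))


class TestCutTree:
    def test_extreme_cuts(self, small_matrix):
        t = ward_linkage_molecules(small_matrix)
        assert cut_tree(t, small_matrix.n_molecules).k == small_matrix.n_molecules
        assert cut_tree(t, 1).k == 1
        with pytest.raises(ValueError, match="out of range"):
            cut_tree(t, 0)

    def test_successive_cuts_differ_by_one_split(self, default_synthetic):
        m, _ = default_synthetic
        t = ward_linkage_molecules(m)
        for k in range(1, 8):
            a = cut_tree(t, k)
            b = cut_tree(t, k + 1)
            # every cluster at k+1 is contained in exactly one cluster at k
            refined = 0
            for c in range(b.k):
                parents = {a.labels[i] for i in np.flatnonzero(b.labels == c)}
                assert len(parents) == 1
            # and exactly one cluster of a splits in two
            from collections import Counter

            mapping = Counter()
            for c in range(a.k):
                children = {b.labels[i] for i in np.flatnonzero(a.labels == c)}
                mapping[len(children)] += 1
            assert mapping[2] == 1 and mapping[1] == a.k - 1

    def test_row_permutation_only_relabels(self, rng, default_synthetic):
        m, _ = default_synthetic
        perm = rng.permutation(m.n_molecules)
        m2 = FreeEnergyMatrix(
            molecule_ids=[m.molecule_ids[i] for i in perm],
            material_ids=m.material_ids,
            values=m.values[perm],
        )
        p1 = cut_tree(ward_linkage_molecules(m), 3)
        p2 = cut_tree(ward_linkage_molecules(m2), 3)
        assert adjusted_rand_score(p1.labels[perm], p2.labels) == pytest.approx(1.0)


class TestKMeans:
    def test_k_equals_n_gives_zero_inertia(self, small_matrix):
        _, inertia = kmeans_partition(small_matrix, small_matrix.n_molecules)
        assert inertia == pytest.approx(0.0, abs=1e-9)

    def test_two_far_blobs_recovered(self, rng):
        X = np.vstack([rng.normal(0, 0.1, (5, 3)), rng.normal(30, 0.1, (5, 3))])
        part, _ = kmeans_partition(matrix_from(X), 2)
        truth = np.array([0] * 5 + [1] * 5)
        assert adjusted_rand_score(part.labels, truth) == 1.0

    def test_k_larger_than_n_rejected(self, small_matrix):
        with pytest.raises(ValueError, match="exceeds"):
            kmeans_partition(small_matrix, 100)

    def test_inertia_non_increasing_in_k(self, default_synthetic):
        m, _ = default_synthetic
        curve = elbow_curve(m, k_max=8)
        assert np.all(np.diff(curve.inertia) <= 1e-7 * max(curve.inertia[0], 1.0))

    def test_elbow_suggests_planted_k(self, default_synthetic):
        m, _ = default_synthetic
        assert elbow_curve(m, k_max=8).suggest_k() == 3


class TestPcaVariance:
    def test_identical_rows_reported_as_zero_components(self):
        m = matrix_from(np.ones((4, 3)) * 2.5)
        v = pca_variance(m)
        assert v.n_components_estimate == 0

    def test_planted_rank_one_dominates(self, rng):
        u = rng.normal(size=8)
        v = rng.normal(size=5)
        X = 10 * np.outer(u, v) + rng.normal(0, 1e-3, (8, 5))
        prof = pca_variance(matrix_from(X))
        assert prof.explained_variance_ratio[0] > 0.99

    def test_ratios_non_increasing_and_sum_to_at_most_one(self, default_synthetic):
        m, _ = default_synthetic
        r = pca_variance(m).explained_variance_ratio
        assert np.all(np.diff(r) <= 1e-12)
        assert r.sum() <= 1.0 + 1e-9
        assert np.all(r >= 0)

    def test_three_planted_groups_give_three_major_components(self, default_synthetic):
        m, _ = default_synthetic
        assert pca_variance(m).n_components_estimate == 3


class TestRepresentatives:
    def test_singleton_cluster_returns_its_member(self):
        m = matrix_from([[0.0, 0.0], [10.0, 10.0], [10.5, 10.0]])
        t = ward_linkage_molecules(m)
        reps = select_representatives(m, cut_tree(t, 2))
        assert "m0" in reps

    def test_point_at_centroid_wins(self):
        # m1 sits exactly at the centroid of the symmetric trio
        m = matrix_from([[-1.0, 0.0], [0.0, 0.0], [1.0, 0.0]])
        part = cut_tree(ward_linkage_molecules(m), 1)
        assert select_representatives(m, part) == ["m1"]

    def test_ward_and_kmeans_agree_on_planted_structure(self, default_synthetic):
        m, labels = default_synthetic
        pw = cut_tree(ward_linkage_molecules(m), 3)
        pk, _ = kmeans_partition(m, 3)
        assert adjusted_rand_score(pw.labels, pk.labels) == 1.0
        assert adjusted_rand_score(pw.labels, labels.molecule_group) == 1.0


def test_newick_export_parses_and_preserves_leaves(default_synthetic):
    m, _ = default_synthetic
    t = ward_linkage_molecules(m)
    nwk = t.to_newick()
    import io

    from Bio import Phylo

    tree = Phylo.read(io.StringIO(nwk), "newick")
    assert sorted(x.name for x in tree.get_terminals()) == sorted(m.molecule_ids)
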