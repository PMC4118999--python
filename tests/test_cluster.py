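"""Hierarchical clustering, silhouette and partition-comparison tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gelclust import (
    DistanceMatrix,
    Partition,
    adjusted_rand_index,
    cut_tree,
    hamming_distance,
    hamming_matrix,
    permutation_validity_test,
    silhouette,
    to_newick,
    ward_linkage,
)
from ward_oracle import brute_force_ward


def _dm(values, ids=None):
    values = np.asarray(values, dtype=float)
    ids = ids or [f"s{i}" for i in range(len(values))]
    return DistanceMatrix(ids, values)


class TestHamming:
    @pytest.mark.parametrize(
        "u, v, expected",
        [
            ([1, 0, 1, 1], [1, 0, 1, 1], 0),
            ([0, 0, 0, 0], [1, 1, 1, 1], 4),
            ([1, 0, 1, 0], [1, 0, 0, 1], 2),
        ],
    )
    def test_bit_counts(self, u, v, expected):
        assert hamming_distance(u, v) == expected
        assert hamming_distance(v, u) == expected

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            hamming_distance([0, 1], [0, 1, 0])

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(0, 2**30 - 1), st.data())
    def test_triangle_inequality(self, seed, data):
        rng = np.random.default_rng(seed)
        u, v, w = rng.integers(0, 2, size=(3, 24))
        assert hamming_distance(u, w) <= hamming_distance(u, v) + hamming_distance(v, w)

    def test_matrix_matches_pairwise(self, rng):
        x = rng.integers(0, 2, size=(6, 30))
        import pandas as pd

        dm = hamming_matrix(pd.DataFrame(x))
        for i in range(6):
            for j in range(6):
                assert dm.values[i, j] == hamming_distance(x[i], x[j])


class TestWardLinkage:
    def test_two_samples_merge_at_their_distance(self):
        dm = _dm([[0, 3.0], [3.0, 0]])
        dend = ward_linkage(dm)
        assert len(dend.merges) == 1
        assert dend.merges[0][:2] == (0, 1)
        assert dend.merges[0][2] == pytest.approx(3.0)

    def test_equidistant_tie_picks_lowest_index_pair(self):
        dm = _dm([[0, 2, 2], [2, 0, 2], [2, 2, 0]])
        dend = ward_linkage(dm)
        assert dend.merges[0][:2] == (0, 1)

    def test_matches_brute_force_centroid_oracle(self, rng):
        """LW recurrence on Hamming distances reproduces the exact
        rational centroid-based Ward agglomeration on binary rows."""
        import pandas as pd

        for _ in range(30):
            n = int(rng.integers(4, 9))
            x = rng.integers(0, 2, size=(n, int(rng.integers(6, 20))))
            dend = ward_linkage(hamming_matrix(pd.DataFrame(x)))
            expected = brute_force_ward(x.astype(float))
            for got, exp in zip(dend.merges, expected):
                assert got[:2] == exp[:2]
                assert got[2] == pytest.approx(exp[2], rel=1e-9)
                assert got[3] == exp[3]

    def test_ward_d2_matches_scipy_on_generic_points(self, rng):
        """The squared-distance variant agrees with an independent Ward
        implementation (scipy) on generic (tie-free) point clouds."""
        from scipy.cluster.hierarchy import fcluster, linkage
        from scipy.spatial.distance import pdist, squareform

        x = rng.normal(size=(12, 4))
        dmat = _dm(squareform(pdist(x)))
        dend = ward_linkage(dmat, variant="ward.D2")
        z = linkage(x, method="ward")
        assert np.allclose(sorted(dend.heights()), sorted(z[:, 2]))
        mine = cut_tree(dend, 3)
        theirs = Partition(
            dmat.sample_ids, fcluster(z, 3, criterion="maxclust").tolist()
        )
        assert adjusted_rand_index(mine, theirs).adjusted_rand == pytest.approx(1.0)

    def test_heights_nondecreasing(self, rng):
        import pandas as pd

        for _ in range(10):
            x = rng.integers(0, 2, size=(10, 25))
            dend = ward_linkage(hamming_matrix(pd.DataFrame(x)))
            h = dend.heights()
            assert np.all(np.diff(h) >= -1e-9)

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0, 1], [2, 0]]))
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0, -1], [-1, 0]]))


class TestCutTree:
    def test_root_and_leaves(self, rng):
        import pandas as pd

        x = rng.integers(0, 2, size=(7, 20))
        dend = ward_linkage(hamming_matrix(pd.DataFrame(x)))
        assert cut_tree(dend, 1).k == 1
        assert cut_tree(dend, 7).k == 7
        with pytest.raises(ValueError):
            cut_tree(dend, 0)
        with pytest.raises(ValueError):
            cut_tree(dend, 8)

    def test_recovers_planted_sizes(self):
        from gelclust import SimulationConfig, simulate_binary_dataset

        binary, truth = simulate_binary_dataset(SimulationConfig(flip_rate=0.02, seed=3))
        part = cut_tree(ward_linkage(hamming_matrix(binary)), 2)
        sizes = sorted(part.labels.count(lab) for lab in set(part.labels))
        assert sizes == [7, 11]

    def test_labels_follow_first_appearance(self, rng):
        import pandas as pd

        x = rng.integers(0, 2, size=(6, 15))
        part = cut_tree(ward_linkage(hamming_matrix(pd.DataFrame(x))), 3)
        assert part.labels[0] == 1  # first sample defines cluster 1
        seen = []
        for lab in part.labels:
            if lab not in seen:
                seen.append(lab)
        assert seen == sorted(seen)


class TestSilhouette:
    def test_hand_computed_widths(self):
        # two pairs: within-pair distance 1, across-pair distance 10
        d = np.array(
            [
                [0, 1, 10, 10],
                [1, 0, 10, 10],
                [10, 10, 0, 1],
                [10, 10, 1, 0],
            ],
            dtype=float,
        )
        p = Partition(["a", "b", "c", "d"], [1, 1, 2, 2])
        widths, mean_w = silhouette(_dm(d, ["a", "b", "c", "d"]), p)
        # every sample: a = 1, b = 10 -> (10 - 1) / 10 = 0.9
        assert np.allclose(widths, 0.9)
        assert mean_w == pytest.approx(0.9)

    def test_matches_sklearn_on_random_data(self, rng):
        from scipy.spatial.distance import pdist, squareform
        from sklearn.metrics import silhouette_samples

        x = rng.normal(size=(15, 3))
        d = squareform(pdist(x))
        labels = rng.integers(1, 4, size=15)
        labels[:3] = [1, 2, 3]  # ensure non-empty clusters
        p = Partition([f"s{i}" for i in range(15)], labels.tolist())
        widths, _mean = silhouette(_dm(d), p)
        expected = silhouette_samples(d, np.asarray(p.labels), metric="precomputed")
        assert np.allclose(widths, expected)

    def test_permutation_null_centers_near_zero(self, rng):
        from scipy.spatial.distance import pdist, squareform

        x = rng.normal(size=(14, 3))
        d = _dm(squareform(pdist(x)))
        means = []
        for _ in range(100):
            labels = rng.permutation([1] * 7 + [2] * 7)
            _w, m = silhouette(d, Partition(d.sample_ids, labels.tolist()))
            means.append(m)
        assert abs(np.mean(means)) < 0.1

    def test_single_cluster_raises(self):
        d = _dm(np.zeros((3, 3)))
        with pytest.raises(ValueError):
            silhouette(d, Partition(d.sample_ids, [1, 1, 1]))


class TestAdjustedRand:
    def test_identical_partitions_score_one(self):
        p = Partition(list("abcdef"), [1, 1, 2, 2, 3, 3])
        assert adjusted_rand_index(p, p).adjusted_rand == pytest.approx(1.0)

    def test_crossed_pairs_score_minus_half(self):
        # all 6 sample pairs disagree maximally between the two partitions
        p1 = Partition(list("abcd"), [1, 1, 2, 2])
        p2 = Partition(list("abcd"), [1, 2, 1, 2])
        assert adjusted_rand_index(p1, p2).adjusted_rand == pytest.approx(-0.5)

    def test_symmetric_and_label_invariant(self, rng):
        from sklearn.metrics import adjusted_rand_score

        ids = [f"s{i}" for i in range(20)]
        for _ in range(10):
            l1 = rng.integers(1, 4, size=20).tolist()
            l2 = rng.integers(1, 4, size=20).tolist()
            p1, p2 = Partition(ids, l1), Partition(ids, l2)
            a = adjusted_rand_index(p1, p2).adjusted_rand
            assert a == pytest.approx(adjusted_rand_index(p2, p1).adjusted_rand)
            # renaming labels leaves the index unchanged
            renamed = Partition(ids, [{1: 7, 2: 5, 3: 9}[v] for v in l1])
            assert adjusted_rand_index(renamed, p2).adjusted_rand == pytest.approx(a)
            # cross-check against an independent implementation
            assert a == pytest.approx(adjusted_rand_score(p1.labels, p2.labels))

    def test_sample_mismatch_raises(self):
        p1 = Partition(["a", "b"], [1, 2])
        p2 = Partition(["a", "c"], [1, 2])
        with pytest.raises(ValueError, match="c"):
            adjusted_rand_index(p1, p2)


class TestPermutationValidity:
    def test_deterministic_for_fixed_seed(self, small_dataset):
        _config, binary, truth = small_dataset
        d = hamming_matrix(binary)
        p = Partition([str(s) for s in binary.index], truth.true_partition.labels)
        p1, _ = permutation_validity_test(d, p, n_perm=99, seed=42)
        p2, _ = permutation_validity_test(d, p, n_perm=99, seed=42)
        assert p1 == p2

    def test_planted_signal_is_significant(self):
        from gelclust import SimulationConfig, simulate_binary_dataset

        binary, truth = simulate_binary_dataset(SimulationConfig(flip_rate=0.02, seed=9))
        d = hamming_matrix(binary)
        p = Partition([str(s) for s in binary.index], truth.true_partition.labels)
        p_value, _ = permutation_validity_test(d, p, n_perm=999, seed=0)
        assert p_value <= 0.01

    def test_random_labels_rarely_significant(self, rng):
        import pandas as pd

        x = rng.integers(0, 2, size=(12, 40))
        d = hamming_matrix(pd.DataFrame(x))
        n_sig = 0
        for s in range(50):
            labels = rng.permutation([1] * 6 + [2] * 6)
            p = Partition(d.sample_ids, labels.tolist())
            p_value, _ = permutation_validity_test(d, p, n_perm=99, seed=s)
            n_sig += p_value <= 0.05
        assert n_sig <= 10  # ~5% expected under the null


def test_newick_roundtrip_structure(small_dataset):
    """The Newick export contains every leaf and parses as a tree."""
    import io as _io

    from Bio import Phylo

    _config, binary, _truth = small_dataset
    dend = ward_linkage(hamming_matrix(binary))
    tree = Phylo.read(_io.StringIO(to_newick(dend)), "newick")
    names = sorted(t.name for t in tree.get_terminals())
    assert names == sorted(str(s) for s in binary.index)
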