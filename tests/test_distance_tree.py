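import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as skbio_nj

from alupopdiv import (
    FrequencyMatrix,
    NeighborJoining,
    distance_matrix,
    nei_distance,
    neighbor_joining,
    path_distance,
    read_newick,
    write_newick,
)
from tests.conftest import random_frequency_matrix


def _fm(rows: dict) -> FrequencyMatrix:
    return FrequencyMatrix(p=pd.DataFrame(rows).T)


class TestDistances:
    @pytest.mark.parametrize("method", ["nei1972", "da1983"])
    def test_identical_profiles_at_zero(self, method):
        m = _fm({"A": [0.3, 0.7, 0.5], "B": [0.3, 0.7, 0.5]})
        assert nei_distance(m, "A", "B", method) == pytest.approx(0.0, abs=1e-12)

    def test_fixed_difference_saturates_da(self):
        m = _fm({"A": [1.0], "B": [0.0]})
        assert nei_distance(m, "A", "B", "da1983") == pytest.approx(1.0)

    def test_fixed_difference_infinite_nei(self):
        m = _fm({"A": [1.0], "B": [0.0]})
        with pytest.raises(ValueError, match="infinite"):
            nei_distance(m, "A", "B", "nei1972")

    def test_two_locus_spreadsheet_oracle(self):
        pa, pb = np.array([0.3, 0.8]), np.array([0.6, 0.5])
        qa, qb = 1 - pa, 1 - pb
        jab = np.mean(pa * pb + qa * qb)
        ja = np.mean(pa**2 + qa**2)
        jb = np.mean(pb**2 + qb**2)
        expected_nei = -np.log(jab / np.sqrt(ja * jb))
        expected_da = 1 - np.mean(np.sqrt(pa * pb) + np.sqrt(qa * qb))
        m = _fm({"A": pa, "B": pb})
        assert nei_distance(m, "A", "B", "nei1972") == pytest.approx(expected_nei, abs=1e-12)
        assert nei_distance(m, "A", "B", "da1983") == pytest.approx(expected_da, abs=1e-12)

    def test_matrix_symmetry_and_labels(self, rng):
        m = random_frequency_matrix(rng, k=6, l=7)
        dm = distance_matrix(m)
        assert list(dm.ids) == m.populations
        assert np.allclose(dm.data, dm.data.T)
        assert np.allclose(np.diag(dm.data), 0.0)
        assert (dm.data >= 0).all()

    def test_unknown_population_rejected(self, rng):
        m = random_frequency_matrix(rng, k=3, l=2)
        with pytest.raises(KeyError):
            nei_distance(m, "pop0", "nope")


def random_additive_case(rng, n_leaves):
    """Random binary tree with positive branch lengths and its path-length matrix."""
    nodes = [TreeNode(name=f"t{i}", length=float(rng.uniform(0.1, 2.0))) for i in range(n_leaves)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = TreeNode(length=float(rng.uniform(0.1, 2.0)))
        parent.extend([nodes[i], nodes[j]])
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [parent]
    root = TreeNode()
    root.extend(nodes)
    dm = root.tip_tip_distances()
    return root, dm


class TestNeighborJoining:
    def test_three_taxa_exact(self):
        dm = DistanceMatrix([[0, 3, 4], [3, 0, 5], [4, 5, 0]], ids=["A", "B", "C"])
        tree = neighbor_joining(dm)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0})

    def test_four_taxon_additive_example(self):
        # generating tree: (A:1, B:2) -- internal 1 -- (C:3, D:4)
        d = np.array([[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], dtype=float)
        dm = DistanceMatrix(d, ids=["A", "B", "C", "D"])
        tree = neighbor_joining(dm)
        # split AB|CD: A and B are siblings
        a = tree.find("A")
        assert {t.name for t in a.parent.tips()} in ({"A", "B"}, {"C", "D"})
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0})
        for x, y, exp in [("A", "B", 3), ("C", "D", 7), ("A", "C", 5), ("B", "D", 7)]:
            assert path_distance(tree, x, y) == pytest.approx(exp)

    def test_additive_consistency_random_trees(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 11))
            truth, dm = random_additive_case(rng, n)
            tree = neighbor_joining(dm)
            for i, a in enumerate(dm.ids):
                for b in dm.ids[i + 1:]:
                    assert path_distance(tree, a, b) == pytest.approx(dm[a, b], abs=1e-9)

    def test_matches_independent_nj_implementation(self, rng):
        truth, dm = random_additive_case(rng, 8)
        mine = neighbor_joining(dm)
        other = skbio_nj(dm)
        for i, a in enumerate(dm.ids):
            for b in dm.ids[i + 1:]:
                assert path_distance(mine, a, b) == pytest.approx(
                    other.find(a).distance(other.find(b)), abs=1e-8
                )

    def test_leaf_set_and_internal_node_count(self, rng):
        _, dm = random_additive_case(rng, 9)
        tree = neighbor_joining(dm)
        assert {t.name for t in tree.tips()} == set(dm.ids)
        internal = [n for n in tree.traverse() if not n.is_tip()]
        assert len(internal) == 9 - 2  # unrooted binary: leaves - 2

    def test_permutation_invariance(self, rng):
        _, dm = random_additive_case(rng, 7)
        perm = rng.permutation(7)
        ids = [dm.ids[i] for i in perm]
        dm2 = DistanceMatrix(dm.data[np.ix_(perm, perm)], ids=ids)
        t1, t2 = neighbor_joining(dm), neighbor_joining(dm2)
        for i, a in enumerate(dm.ids):
            for b in dm.ids[i + 1:]:
                assert path_distance(t1, a, b) == pytest.approx(path_distance(t2, a, b), abs=1e-9)

    def test_equal_distances_star(self):
        d = np.full((4, 4), 2.0)
        np.fill_diagonal(d, 0.0)
        tree = neighbor_joining(DistanceMatrix(d, ids=list("ABCD")))
        total = sum(n.length or 0.0 for n in tree.traverse() if n.length is not None)
        assert total == pytest.approx(4.0)  # four tips at d/2, zero internal edge

    def test_negative_entry_rejected(self):
        d = np.array([[0, -1.0, 1], [-1.0, 0, 1], [1, 1, 0]])
        with pytest.raises(ValueError, match="negative"):
            neighbor_joining(d)

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError, match="3 taxa"):
            neighbor_joining(np.array([[0.0, 1.0], [1.0, 0.0]]))

    def test_negative_branch_clamped_preserving_pair_sum(self):
        # deliberately non-additive matrix known to drive a branch negative
        d = np.array(
            [[0.0, 0.869, 0.657, 0.390], [0.869, 0.0, 0.610, 0.257],
             [0.657, 0.610, 0.0, 0.164], [0.390, 0.257, 0.164, 0.0]]
        )
        with pytest.warns(UserWarning, match="clamped"):
            tree = neighbor_joining(DistanceMatrix(d, ids=list("ABCD")))
        for tip in tree.tips():
            assert tip.length >= 0.0


class TestNewickAndEstimator:
    def test_newick_round_trip(self, tmp_path, rng):
        _, dm = random_additive_case(rng, 6)
        tree = neighbor_joining(dm)
        path = tmp_path / "tree.nwk"
        write_newick(tree, path)
        back = read_newick(path)
        for i, a in enumerate(dm.ids):
            for b in dm.ids[i + 1:]:
                assert path_distance(back, a, b) == pytest.approx(path_distance(tree, a, b), abs=1e-9)

    def test_unknown_leaf_lookup(self, rng):
        _, dm = random_additive_case(rng, 5)
        tree = neighbor_joining(dm)
        with pytest.raises(KeyError):
            path_distance(tree, "t0", "zzz")

    def test_estimator_from_frequencies(self, sim_frequencies):
        est = NeighborJoining(metric="nei1972").fit(sim_frequencies)
        assert {t.name for t in est.tree_.tips()} == set(sim_frequencies.populations)
        assert est.newick_.endswith(";")

    def test_estimator_precomputed(self, rng):
        _, dm = random_additive_case(rng, 5)
        est = NeighborJoining(metric="precomputed").fit(dm)
        assert est.labels_ == list(dm.ids)

    def test_estimator_rejects_array_without_precomputed(self, rng):
        with pytest.raises(TypeError):
            NeighborJoining(metric="nei1972").fit(np.eye(4))
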