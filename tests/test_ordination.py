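"""Distances, NJ trees, UniFrac (with naive oracle), PCoA, group distances."""

import itertools

import numpy as np
import pytest
from skbio import TreeNode

from algscreen.io import SequenceRecord
from algscreen.ordination import (
    DistanceMatrix,
    group_distance_comparison,
    nj_tree,
    pairwise_distance,
    pcoa,
    unweighted_unifrac,
    weighted_unifrac,
)


def random_tree(n_leaves, rng, min_len=0.1, max_len=2.0):
    """Random rooted binary tree with uniform random branch lengths."""
    nodes = [TreeNode(name=f"L{i}") for i in range(n_leaves)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        a.length = float(rng.uniform(min_len, max_len))
        b.length = float(rng.uniform(min_len, max_len))
        nodes.append(TreeNode(children=[a, b]))
    return nodes[0]


def naive_unweighted_unifrac(tree, set_a, set_b):
    """Branch-partition definition evaluated branch by branch."""
    unique = total = 0.0
    for node in tree.traverse(include_self=False):
        leaves = {t.name for t in node.tips()} or {node.name}
        in_a = bool(leaves & set_a)
        in_b = bool(leaves & set_b)
        length = node.length or 0.0
        if in_a or in_b:
            total += length
            if in_a != in_b:
                unique += length
    return unique / total if total else 0.0


def naive_weighted_unifrac(tree, abund_a, abund_b, normalized=True):
    ta, tb = sum(abund_a.values()), sum(abund_b.values())
    raw = width = 0.0
    for node in tree.traverse(include_self=False):
        leaves = {t.name for t in node.tips()} or {node.name}
        pa = sum(abund_a.get(l, 0.0) for l in leaves) / ta
        pb = sum(abund_b.get(l, 0.0) for l in leaves) / tb
        length = node.length or 0.0
        raw += length * abs(pa - pb)
        width += length * (pa + pb)
    if not normalized:
        return raw
    return raw / width if width else 0.0


class TestPairwiseDistance:
    def test_identical_pair(self, make_records):
        d = pairwise_distance(make_records(["AAAA", "AAAA"]))
        assert d.data[0, 1] == 0.0

    def test_single_difference(self, make_records):
        d = pairwise_distance(make_records(["AAAA", "AAAT"]))
        assert d.data[0, 1] == pytest.approx(0.25)

    def test_pairwise_gap_exclusion(self, make_records):
        # gap column excluded pairwise: comparable columns 0,1,3, of
        # which only column 1 differs
        d = pairwise_distance(make_records(["AA-A", "ACTA"]))
        assert d.data[0, 1] == pytest.approx(1 / 3)
        # when the gap column is the only difference the distance is 0
        d = pairwise_distance(make_records(["AA-A", "AATA"]))
        assert d.data[0, 1] == 0.0

    def test_length_mismatch_is_error(self, make_records):
        with pytest.raises(ValueError, match="equal length"):
            pairwise_distance(make_records(["AAA", "AAAA"]))


class TestNeighborJoining:
    def test_two_taxa_branch_pair(self):
        t = nj_tree(DistanceMatrix(["A", "B"], np.array([[0, 1.0], [1.0, 0]])))
        assert sum(n.length or 0 for n in t.traverse(include_self=False)) == pytest.approx(1.0)

    def test_three_taxon_closed_form(self):
        d = DistanceMatrix(
            ["A", "B", "C"],
            np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], dtype=float),
        )
        t = nj_tree(d)
        pendant = {tip.name: tip.length for tip in t.tips()}
        assert pendant == pytest.approx({"A": 1.0, "B": 1.0, "C": 3.0})

    @pytest.mark.parametrize("n_leaves", [4, 5, 6, 8])
    def test_additive_matrix_recovery(self, n_leaves, rng):
        """Path-length matrices of random trees are reproduced exactly."""
        for _ in range(10):
            tree = random_tree(n_leaves, rng)
            labels = sorted(t.name for t in tree.tips())
            d = np.zeros((n_leaves, n_leaves))
            for i, a in enumerate(labels):
                for j in range(i + 1, n_leaves):
                    d[i, j] = d[j, i] = tree.find(a).distance(tree.find(labels[j]))
            recovered = nj_tree(DistanceMatrix(labels, d))
            for i, a in enumerate(labels):
                for j in range(i + 1, n_leaves):
                    got = recovered.find(a).distance(recovered.find(labels[j]))
                    assert got == pytest.approx(d[i, j], abs=1e-9)

    def test_matches_scikit_bio_path_lengths(self, rng):
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        tree = random_tree(6, rng)
        labels = sorted(t.name for t in tree.tips())
        d = np.zeros((6, 6))
        for i, a in enumerate(labels):
            for j in range(i + 1, 6):
                d[i, j] = d[j, i] = tree.find(a).distance(tree.find(labels[j]))
        ours = nj_tree(DistanceMatrix(labels, d))
        theirs = skbio_nj(SkbioDM(d, labels))
        for a, b in itertools.combinations(labels, 2):
            assert ours.find(a).distance(ours.find(b)) == pytest.approx(
                theirs.find(a).distance(theirs.find(b)), abs=1e-9
            )

    def test_asymmetric_matrix_is_error(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(["A", "B"], np.array([[0, 1.0], [2.0, 0]]))


class TestUnweightedUnifrac:
    def test_identical_sets_zero(self, rng):
        tree = random_tree(5, rng)
        leaves = {t.name for t in tree.tips()}
        assert unweighted_unifrac(tree, leaves, leaves) == 0.0

    def test_disjoint_sets_on_star_tree(self):
        tree = TreeNode.read(["(A:1,B:1,C:1,D:1);"])
        assert unweighted_unifrac(tree, {"A", "B"}, {"C", "D"}) == 1.0

    def test_star_tree_partial_overlap(self):
        # A={1,2}, B={2,3}: unique branches 1 and 3, union covers 1,2,3
        tree = TreeNode.read(["(L1:1,L2:1,L3:1,L4:1);"])
        assert unweighted_unifrac(tree, {"L1", "L2"}, {"L2", "L3"}) == pytest.approx(2 / 3)

    def test_empty_sample_is_error(self, rng):
        tree = random_tree(4, rng)
        with pytest.raises(ValueError, match="empty"):
            unweighted_unifrac(tree, set(), {"L0"})

    def test_agrees_with_naive_oracle_exhaustively(self, rng):
        """Postorder accumulation equals the branch-partition definition on
        random trees up to 6 leaves over every presence-set pair."""
        for n_leaves in range(2, 7):
            tree = random_tree(n_leaves, rng)
            leaves = [t.name for t in tree.tips()]
            subsets = [
                set(c)
                for r in range(1, n_leaves + 1)
                for c in itertools.combinations(leaves, r)
            ]
            for sa in subsets:
                for sb in subsets:
                    assert unweighted_unifrac(tree, sa, sb) == pytest.approx(
                        naive_unweighted_unifrac(tree, sa, sb)
                    )

    def test_midpoint_rooting_is_stable(self, rng):
        """Re-applying midpoint rooting leaves the distance unchanged, so
        the pipeline's fixed rooting convention is reproducible."""
        tree = random_tree(6, rng).root_at_midpoint()
        leaves = [t.name for t in tree.tips()]
        sa, sb = set(leaves[:4]), set(leaves[2:])
        again = tree.root_at_midpoint()
        assert unweighted_unifrac(tree, sa, sb) == pytest.approx(
            unweighted_unifrac(again, sa, sb)
        )

    def test_raw_weighted_unifrac_is_rooting_invariant(self, rng):
        """The unnormalized weighted distance does not depend on root
        placement (complementary branch masses contribute equally)."""
        tree = random_tree(6, rng)
        leaves = [t.name for t in tree.tips()]
        a = {l: float(rng.integers(1, 30)) for l in leaves}
        b = {l: float(rng.integers(1, 30)) for l in leaves}
        rerooted = tree.copy().root_at_midpoint()
        assert weighted_unifrac(tree, a, b, normalized=False) == pytest.approx(
            weighted_unifrac(rerooted, a, b, normalized=False)
        )


class TestWeightedUnifrac:
    def test_identical_abundances_zero(self, rng):
        tree = random_tree(5, rng)
        ab = {t.name: float(i + 1) for i, t in enumerate(tree.tips())}
        assert weighted_unifrac(tree, ab, ab) == pytest.approx(0.0)

    def test_two_leaf_complete_separation(self):
        tree = TreeNode.read(["(A:1,B:1);"])
        assert weighted_unifrac(tree, {"A": 5.0}, {"B": 3.0}) == pytest.approx(1.0)
        assert weighted_unifrac(tree, {"A": 5.0}, {"B": 3.0}, normalized=False) == pytest.approx(2.0)

    def test_scale_invariance(self, rng):
        tree = random_tree(6, rng)
        leaves = [t.name for t in tree.tips()]
        a = {l: float(rng.integers(1, 50)) for l in leaves[:4]}
        b = {l: float(rng.integers(1, 50)) for l in leaves[2:]}
        a10 = {l: 10 * v for l, v in a.items()}
        assert weighted_unifrac(tree, a, b) == pytest.approx(
            weighted_unifrac(tree, a10, b)
        )

    def test_agrees_with_naive_oracle(self, rng):
        for n_leaves in (3, 4, 5, 6):
            tree = random_tree(n_leaves, rng)
            leaves = [t.name for t in tree.tips()]
            for _ in range(20):
                a = {l: float(rng.integers(0, 20)) for l in leaves}
                b = {l: float(rng.integers(0, 20)) for l in leaves}
                if sum(a.values()) == 0 or sum(b.values()) == 0:
                    continue
                for normalized in (True, False):
                    assert weighted_unifrac(tree, a, b, normalized) == pytest.approx(
                        naive_weighted_unifrac(tree, a, b, normalized)
                    )

    def test_zero_total_is_error(self, rng):
        tree = random_tree(3, rng)
        with pytest.raises(ValueError, match="zero-total"):
            weighted_unifrac(tree, {"L0": 0.0}, {"L1": 1.0})

    def test_metric_axioms_on_random_instances(self, rng):
        tree = random_tree(5, rng)
        leaves = [t.name for t in tree.tips()]
        comms = [
            {l: float(rng.integers(1, 30)) for l in leaves} for _ in range(4)
        ]
        for a, b in itertools.combinations(comms, 2):
            dab = weighted_unifrac(tree, a, b)
            assert dab >= 0
            assert dab == pytest.approx(weighted_unifrac(tree, b, a))


class TestPcoa:
    def test_collinear_points_single_positive_eigenvalue(self):
        d = DistanceMatrix(
            ["a", "b", "c"],
            np.array([[0, 3, 5], [3, 0, 2], [5, 2, 0]], dtype=float),
        )
        result = pcoa(d)
        assert len(result.eigenvalues) == 1
        coords = result.coordinates
        for i, j in itertools.combinations(range(3), 2):
            got = np.linalg.norm(coords[i] - coords[j])
            assert got == pytest.approx(d.data[i, j], abs=1e-9)

    def test_identical_points_coincide(self):
        d = DistanceMatrix(
            ["a", "b", "c"],
            np.array([[0, 0, 1.0], [0, 0, 1.0], [1.0, 1.0, 0]]),
        )
        result = pcoa(d)
        assert np.allclose(result.coordinates[0], result.coordinates[1], atol=1e-9)

    def test_euclidean_inputs_reproduced(self, rng):
        """Full-space coordinates of a Euclidean distance matrix reproduce
        the inputs to 1e-9."""
        for _ in range(10):
            pts = rng.normal(size=(7, 3))
            d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
            result = pcoa(DistanceMatrix([f"p{i}" for i in range(7)], d))
            coords = result.coordinates
            for i, j in itertools.combinations(range(7), 2):
                assert np.linalg.norm(coords[i] - coords[j]) == pytest.approx(
                    d[i, j], abs=1e-9
                )

    def test_double_centering_zero_means(self, rng):
        pts = rng.normal(size=(6, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        n = 6
        j = np.eye(n) - np.ones((n, n)) / n
        b = -0.5 * j @ (d**2) @ j
        assert np.allclose(b.mean(axis=0), 0, atol=1e-10)
        assert np.allclose(b.mean(axis=1), 0, atol=1e-10)
        result = pcoa(DistanceMatrix([f"p{i}" for i in range(n)], d))
        assert np.allclose(result.coordinates.mean(axis=0), 0, atol=1e-9)

    def test_explained_fractions_sum_to_one_or_less(self, rng):
        pts = rng.normal(size=(5, 4))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        result = pcoa(DistanceMatrix([f"p{i}" for i in range(5)], d))
        assert result.explained.sum() <= 1 + 1e-12

    def test_single_point_is_error(self):
        with pytest.raises(ValueError):
            pcoa(DistanceMatrix(["a"], np.zeros((1, 1))))


class TestGroupDistanceComparison:
    def test_pair_counting(self):
        labels = ["w1", "w2", "r1", "r2"]
        d = np.array(
            [
                [0, 1, 2, 3],
                [1, 0, 4, 5],
                [2, 4, 0, 6],
                [3, 5, 6, 0],
            ],
            dtype=float,
        )
        groups = {"w1": "W", "w2": "W", "r1": "R", "r2": "R"}
        res = group_distance_comparison(DistanceMatrix(labels, d), groups, "W", "R")
        assert len(res["distances"]["within_a"]) == 1
        assert len(res["distances"]["within_b"]) == 1
        assert len(res["distances"]["between"]) == 4

    def test_zero_matrix_all_ns(self):
        labels = ["w1", "w2", "r1", "r2"]
        groups = {"w1": "W", "w2": "W", "r1": "R", "r2": "R"}
        res = group_distance_comparison(
            DistanceMatrix(labels, np.zeros((4, 4))), groups, "W", "R"
        )
        assert all(not t.significant for t in res["tests"].values())

    def test_unknown_label_is_error(self):
        labels = ["w1", "w2", "r1"]
        d = np.zeros((3, 3))
        with pytest.raises(ValueError):
            group_distance_comparison(
                DistanceMatrix(labels, d), {"w1": "W", "w2": "W", "r1": "X"}, "W", "R"
            )
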