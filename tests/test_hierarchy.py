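"""Posture ontology: structure, label codec, tree-descent decoding, distances."""

import itertools

import numpy as np
import pytest

from drhn.hierarchy import (
    PostureNode,
    PostureTree,
    build_default_tree,
    decode_prediction,
    encode_label,
    load_tree,
    root_label,
    semantic_distance,
)

LEAVES = [
    "sitting straight",
    "lightly hunched",
    "hunched over",
    "extremely hunched",
    "partially lying",
    "lying down",
]


def brute_force_decode(tree, scores):
    """Oracle: enumerate all root-to-leaf paths and replay stagewise argmax.

    Independent of the implementation's recursion: for each level it keeps
    only paths through the best-scoring node among the candidates at that
    level, using first-in-order tie-breaks.
    """
    paths = []
    def walk(node, acc):
        acc = acc + [node]
        if node.is_leaf:
            paths.append(acc)
        for c in node.children:
            walk(c, acc)
    for r in tree.roots:
        walk(r, [])
    survivors = paths
    depth = 0
    while len(survivors) > 1:
        candidates = []
        for p in survivors:
            n = p[min(depth, len(p) - 1)]
            if n not in candidates:
                candidates.append(n)
        best = max(candidates, key=lambda n: (scores[n.index], -n.index))
        survivors = [p for p in survivors if p[min(depth, len(p) - 1)] is best]
        depth += 1
    return survivors[0][-1].name


class TestDefaultTree:
    def test_leaf_set_and_node_count(self, tree):
        assert sorted(tree.leaf_names) == sorted(LEAVES)
        assert tree.n_nodes == 8  # matches the network's output width

    def test_breadth_first_index_order(self, tree):
        names = [n.name for n in tree.nodes]
        assert names == [
            "sitting straight", "forward posture", "backward posture",
            "lightly hunched", "hunched over", "extremely hunched",
            "partially lying", "lying down",
        ]
        assert [n.index for n in tree.nodes] == list(range(8))

    def test_path_depths(self, tree):
        assert len(tree.path_to("sitting straight")) == 1
        assert len(tree.path_to("hunched over")) == 2

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            PostureTree([PostureNode("a"), PostureNode("a")])

    def test_load_tree_from_mapping(self):
        t = load_tree({"roots": [
            {"name": "x", "children": [{"name": "y"}, {"name": "z"}]},
        ]})
        assert t.leaf_names == ["y", "z"]
        assert t.n_nodes == 3


class TestEncode:
    @pytest.mark.parametrize("leaf,active", [
        ("hunched over", {"forward posture", "hunched over"}),
        ("sitting straight", {"sitting straight"}),
        ("lying down", {"backward posture", "lying down"}),
    ])
    def test_path_activation(self, tree, leaf, active):
        vec = encode_label(tree, leaf)
        on = {n.name for n in tree.nodes if vec[n.index] == 1.0}
        assert on == active
        assert vec.sum() == len(active)

    def test_every_truth_vector_is_path_consistent(self, tree):
        for leaf in tree.leaf_names:
            vec = encode_label(tree, leaf)
            assert set(np.unique(vec)) <= {0.0, 1.0}
            assert 1 <= vec.sum() <= 2
            for node in tree.nodes:
                if vec[node.index] == 1.0 and (p := tree.parent(node.name)):
                    assert vec[p.index] == 1.0  # child active => parent active

    def test_unknown_leaf_rejected(self, tree):
        with pytest.raises(KeyError, match="levitating"):
            encode_label(tree, "levitating")

    def test_internal_node_rejected(self, tree):
        with pytest.raises(ValueError, match="forward posture"):
            encode_label(tree, "forward posture")


class TestDecode:
    def test_stagewise_argmax_example(self, tree):
        scores = np.array([0.05, 0.90, 0.20, 0.30, 0.80, 0.10, 0.0, 0.0])
        path = decode_prediction(tree, scores)
        assert path.leaf == "hunched over"
        assert path.root_branch == "forward posture"
        assert path.nodes == ["forward posture", "hunched over"]
        assert path.combined_confidence == pytest.approx(0.85)

    def test_round_trip_for_every_leaf(self, tree):
        for leaf in tree.leaf_names:
            path = decode_prediction(tree, encode_label(tree, leaf))
            assert path.leaf == leaf
            assert path.combined_confidence == pytest.approx(1.0)

    def test_matches_path_enumeration_oracle(self, tree, rng):
        for _ in range(1000):
            scores = rng.random(8)
            assert decode_prediction(tree, scores).leaf == brute_force_decode(
                tree, scores
            )

    def test_tie_breaks_by_node_order(self, tree):
        path = decode_prediction(tree, np.full(8, 0.5))
        assert path.leaf == "sitting straight"  # first root in fixed order

    def test_wrong_length_rejected(self, tree):
        with pytest.raises(ValueError, match="length"):
            decode_prediction(tree, np.ones(5))

    def test_confidence_is_path_mean(self, tree, rng):
        scores = rng.random(8)
        path = decode_prediction(tree, scores)
        expect = np.mean([scores[tree.node(n).index] for n in path.nodes])
        assert path.combined_confidence == pytest.approx(expect)


class TestSemanticDistance:
    def bfs_oracle(self, tree, a, b):
        """Independent breadth-first search over the undirected tree graph
        (root branches joined through a virtual super-root)."""
        adj = {"__root__": [r.name for r in tree.roots]}
        for node in tree.nodes:
            adj.setdefault(node.name, [])
            for c in node.children:
                adj[node.name].append(c.name)
                adj.setdefault(c.name, []).append(node.name)
            parent = tree.parent(node.name)
            if parent is None:
                adj[node.name].append("__root__")
        frontier, dist = [a], 0
        seen = {a}
        while frontier:
            if b in frontier:
                return dist
            frontier = [y for x in frontier for y in adj[x] if y not in seen]
            seen.update(frontier)
            dist += 1
        raise AssertionError("disconnected tree")

    def test_identity(self, tree):
        assert semantic_distance(tree, "lying down", "lying down") == 0

    def test_sibling_error_smaller_than_cross_branch(self, tree):
        near = semantic_distance(tree, "lying down", "partially lying")
        far = semantic_distance(tree, "lying down", "hunched over")
        assert near < far

    def test_all_pairs_match_bfs_oracle(self, tree):
        for a, b in itertools.combinations(tree.leaf_names, 2):
            d = semantic_distance(tree, a, b)
            assert d == self.bfs_oracle(tree, a, b)
            assert d == semantic_distance(tree, b, a)  # symmetry

    def test_metric_triangle_inequality(self, tree):
        leaves = tree.leaf_names
        for a, b, c in itertools.product(leaves, repeat=3):
            assert semantic_distance(tree, a, c) <= (
                semantic_distance(tree, a, b) + semantic_distance(tree, b, c)
            )

    def test_non_leaf_rejected(self, tree):
        with pytest.raises(ValueError, match="forward posture"):
            semantic_distance(tree, "forward posture", "lying down")


class TestRootLabel:
    @pytest.mark.parametrize("leaf,root", [
        ("extremely hunched", "forward posture"),
        ("sitting straight", "straight posture"),
        ("partially lying", "backward posture"),
        ("lightly hunched", "forward posture"),
        ("lying down", "backward posture"),
    ])
    def test_collapse(self, tree, leaf, root):
        assert root_label(tree, leaf) == root

    def test_unknown_rejected(self, tree):
        with pytest.raises(KeyError):
            root_label(tree, "unknown")
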