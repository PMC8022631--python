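"""Posture ontology: tree definition, flattened label codec, tree-descent decoding.

The sitting-posture label set is organised as a small ontology tree with three
top-level branches (straight / forward / backward posture).  A posture label
is a *leaf* of the tree; its flattened encoding activates every node on the
root-to-leaf path, turning the 6-class problem into an 8-unit multi-label one.
Decoding walks the tree greedily from the roots, picking the highest-scoring
child at each level, so an uncertain fine-grained score can never override the
branch-level decision ("semantic lock").

The codec is generic over trees of any depth; the 8-node posture tree shipped
in ``resources/posture_tree.yaml`` is the default, tested instance.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "PostureNode",
    "PostureTree",
    "PredictedPath",
    "build_default_tree",
    "load_tree",
    "encode_label",
    "decode_prediction",
    "semantic_distance",
    "root_label",
]


@dataclass
class PostureNode:
    """One node of the posture ontology.

    ``branch`` is the label used when the node is reported as a root branch;
    it differs from ``name`` only for merged branch/leaf nodes (the default
    tree's "sitting straight", reported as "straight posture" at root level).
    """

    name: str
    children: list["PostureNode"] = field(default_factory=list)
    index: int = -1
    branch: str | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def branch_label(self) -> str:
        return self.branch if self.branch is not None else self.name


class PostureTree:
    """Ordered forest of :class:`PostureNode` roots with flattened indices.

    Indices are assigned breadth-first in document order: all roots first,
    then the children of each root in order, and so on.  The index order is
    frozen — it defines the meaning of each unit of the network's output
    layer and of serialized label vectors.
    """

    def __init__(self, roots: list[PostureNode]):
        if not roots:
            raise ValueError("tree must have at least one root")
        self.roots = roots
        self._by_name: dict[str, PostureNode] = {}
        self._parent: dict[str, PostureNode | None] = {}
        # breadth-first index assignment
        order: list[PostureNode] = []
        frontier: list[tuple[PostureNode, PostureNode | None]] = [
            (r, None) for r in roots
        ]
        while frontier:
            nxt: list[tuple[PostureNode, PostureNode | None]] = []
            for node, parent in frontier:
                if node.name in self._by_name:
                    raise ValueError(f"duplicate node name: {node.name!r}")
                self._by_name[node.name] = node
                self._parent[node.name] = parent
                order.append(node)
                nxt.extend((c, node) for c in node.children)
            frontier = nxt
        for i, node in enumerate(order):
            node.index = i
        self._order = order

    @property
    def n_nodes(self) -> int:
        return len(self._order)

    @property
    def nodes(self) -> list[PostureNode]:
        return list(self._order)

    @property
    def leaf_names(self) -> list[str]:
        return [n.name for n in self._order if n.is_leaf]

    def node(self, name: str) -> PostureNode:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"unknown node name: {name!r}") from None

    def parent(self, name: str) -> PostureNode | None:
        self.node(name)
        return self._parent[name]

    def path_to(self, name: str) -> list[PostureNode]:
        """Root-to-node list of nodes."""
        node = self.node(name)
        path = [node]
        while (p := self._parent[path[0].name]) is not None:
            path.insert(0, p)
        return path

    def __repr__(self) -> str:  # pragma: no cover
        return f"PostureTree({self.n_nodes} nodes, {len(self.leaf_names)} leaves)"


@dataclass
class PredictedPath:
    """A decoded root-to-leaf prediction with its per-node scores."""

    nodes: list[str]
    leaf: str
    root_branch: str
    per_node_scores: list[float]
    combined_confidence: float


def _parse_node(spec: dict) -> PostureNode:
    children = [_parse_node(c) for c in spec.get("children", [])]
    return PostureNode(
        name=spec["name"], children=children, branch=spec.get("branch")
    )


def load_tree(source) -> PostureTree:
    """Build a tree from a YAML mapping ``{roots: [{name, branch?, children?}]}``.

    ``source`` may be a path, an open file, or an already-parsed mapping.
    """
    if isinstance(source, dict):
        doc = source
    elif hasattr(source, "read"):
        doc = yaml.safe_load(source)
    else:
        with open(source) as fh:
            doc = yaml.safe_load(fh)
    return PostureTree([_parse_node(r) for r in doc["roots"]])


def build_default_tree() -> PostureTree:
    """The shipped 8-node / 6-leaf sitting-posture ontology.

    Flattened index order: sitting straight (0), forward posture (1),
    backward posture (2), lightly hunched (3), hunched over (4),
    extremely hunched (5), partially lying (6), lying down (7).
    """
    ref = importlib.resources.files("drhn.resources") / "posture_tree.yaml"
    with ref.open() as fh:
        return load_tree(fh)


def encode_label(tree: PostureTree, leaf: str) -> np.ndarray:
    """Binary flattened vector activating the leaf's whole root-to-leaf path."""
    node = tree.node(leaf)
    if not node.is_leaf:
        raise ValueError(f"{leaf!r} is not a leaf of the tree")
    vec = np.zeros(tree.n_nodes, dtype=np.float64)
    for n in tree.path_to(leaf):
        vec[n.index] = 1.0
    return vec


def decode_prediction(tree: PostureTree, scores: np.ndarray) -> PredictedPath:
    """Greedy tree descent: argmax over roots, then over children, to a leaf.

    Ties are broken by the frozen node order (first wins).  The combined
    confidence is the arithmetic mean of the scores along the chosen path.
    """
    scores = np.asarray(scores, dtype=np.float64).ravel()
    if scores.shape[0] != tree.n_nodes:
        raise ValueError(
            f"score vector has length {scores.shape[0]}, tree has {tree.n_nodes} nodes"
        )
    level = tree.roots
    path: list[PostureNode] = []
    while level:
        best = level[int(np.argmax([scores[n.index] for n in level]))]
        path.append(best)
        level = best.children
    vals = [float(scores[n.index]) for n in path]
    return PredictedPath(
        nodes=[n.name for n in path],
        leaf=path[-1].name,
        root_branch=path[0].branch_label,
        per_node_scores=vals,
        combined_confidence=float(np.mean(vals)),
    )


def semantic_distance(tree: PostureTree, leaf_a: str, leaf_b: str) -> int:
    """Shortest-path length between two leaves in the ontology tree.

    The three root branches are joined through a virtual super-root, so
    sibling leaves are always closer than leaves of different branches —
    the distance grades how severe a misclassification is semantically.
    """
    for name in (leaf_a, leaf_b):
        if not tree.node(name).is_leaf:
            raise ValueError(f"{name!r} is not a leaf of the tree")
    pa = [n.name for n in tree.path_to(leaf_a)]
    pb = [n.name for n in tree.path_to(leaf_b)]
    common = 0
    for x, y in zip(pa, pb):
        if x != y:
            break
        common += 1
    # paths hang off a shared virtual super-root when they share no prefix
    return (len(pa) - common) + (len(pb) - common)


def root_label(tree: PostureTree, leaf: str) -> str:
    """The root-branch label (straight/forward/backward posture) of a leaf."""
    node = tree.node(leaf)
    if not node.is_leaf:
        raise ValueError(f"{leaf!r} is not a leaf of the tree")
    return tree.path_to(leaf)[0].branch_label
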