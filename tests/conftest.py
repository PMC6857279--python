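"""Shared fixtures and random-tree generators for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from phylortho.tree_io import GeneTree, TreeNode, assign_node_ids, read_species_tree


@pytest.fixture
def simple_species_tree():
    """((x,y),o): two in-group species and one out-group species."""
    return read_species_tree("((x,y),o);")


@pytest.fixture
def four_species_tree():
    """(((A,B),C),D): the ladder used by the resolver examples."""
    return read_species_tree("(((A,B),C),D);")


@pytest.fixture
def six_species_tree():
    """Four in-group species and a two-species out-group clade."""
    return read_species_tree("(((a,b),(c,d)),(o1,o2));")


def make_leaf(label: str) -> TreeNode:
    node = TreeNode(label=label)
    node.species = label.split("_", 1)[0]
    return node


def join(*subtrees: TreeNode) -> TreeNode:
    node = TreeNode()
    for s in subtrees:
        node.add_child(s)
    return node


def random_rooted_topology(rng: np.random.Generator,
                           labels: list[str]) -> TreeNode:
    """Random binary topology over the given leaf labels (joined pairwise
    in random order)."""
    nodes = [make_leaf(l) for l in labels]
    while len(nodes) > 1:
        i = int(rng.integers(len(nodes)))
        a = nodes.pop(i)
        j = int(rng.integers(len(nodes)))
        b = nodes.pop(j)
        nodes.append(join(a, b))
    return nodes[0]


def random_gene_tree(rng: np.random.Generator, n_leaves: int,
                     species_pool: list[str], rooted: bool = True) -> GeneTree:
    """Random gene tree with species drawn uniformly from the pool."""
    species = [species_pool[int(rng.integers(len(species_pool)))]
               for _ in range(n_leaves)]
    labels = [f"{sp}_g{i}" for i, sp in enumerate(species)]
    root = random_rooted_topology(rng, labels)
    assign_node_ids(root)
    return GeneTree(root=root, rooted=rooted,
                    labels={l: None for l in labels})


def all_shapes(n: int) -> list:
    """All rooted binary tree shapes with ``n`` leaves, as nested tuples
    (a leaf is the integer 0); unordered children, so no duplicates."""
    if n == 1:
        return [0]
    out = []
    seen = set()
    for i in range(1, n // 2 + 1):
        for left in all_shapes(i):
            for right in all_shapes(n - i):
                norm = tuple(sorted((repr(left), repr(right))))
                if norm in seen:
                    continue
                seen.add(norm)
                out.append((left, right))
    return out


def shape_to_tree(shape, species_assignment: list[str]) -> TreeNode:
    """Materialise a shape with the given per-leaf species (consumed left
    to right); gene ids are unique within the tree."""
    it = iter(range(len(species_assignment)))

    def rec(s) -> TreeNode:
        if s == 0:
            i = next(it)
            return make_leaf(f"{species_assignment[i]}_g{i}")
        return join(rec(s[0]), rec(s[1]))

    root = rec(shape)
    assign_node_ids(root)
    return root


def count_leaves(shape) -> int:
    if shape == 0:
        return 1
    return count_leaves(shape[0]) + count_leaves(shape[1])
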