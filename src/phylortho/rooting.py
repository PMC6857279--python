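"""Outgroup rooting of unrooted gene trees against a rooted species tree.

Tree-inference programs emit unrooted gene trees, but orthology inference
needs the root: it decides which divergence is oldest and therefore which
nodes separate in-group from out-group lineages.  Given the rooted species
tree, the species present in a gene tree induce an in-group/out-group split
(O, I).  Every bipartition (edge) of the gene tree is then scored with two
complementary products over the species sets A and B found on its two sides:

    S_IO = (|O∩A|/|O|) (|I∩B|/|I|) (1 − |O∩B|/|O|) (1 − |I∩A|/|I|)
    S_AD = (|O∩A|/|O|) (|I∩B|/|I|) (|O∩B|/|O|) (|I∩A|/|I|)

S_IO is 1 exactly when the edge perfectly separates out-group genes from
in-group genes (the classic outgroup root); S_AD is 1 exactly when both sides
contain every species — the signature of a gene duplication that predates all
the speciations, which is then itself the correct root.  Both scores lie in
[0, 1], and a perfect score for one implies the other is 0 on every edge of
the tree.  The edge maximising max(S_IO, S_AD) is chosen as the root.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Optional

from .tree_io import GeneTree, SpeciesTree, TreeNode, assign_node_ids

log = logging.getLogger("phylortho.rooting")

__all__ = [
    "InOutSplit",
    "RootScore",
    "induced_split",
    "score_bipartition",
    "root_gene_tree",
]


@dataclass(frozen=True)
class InOutSplit:
    """The out-group (O) / in-group (I) species split induced by the species
    tree on the species actually present in a gene tree."""

    outgroup: frozenset[str]
    ingroup: frozenset[str]

    def __post_init__(self):
        if not self.outgroup or not self.ingroup:
            raise ValueError("both out-group and in-group must be non-empty")
        if self.outgroup & self.ingroup:
            raise ValueError("out-group and in-group overlap")


@dataclass(frozen=True)
class RootScore:
    """The (S_IO, S_AD) pair of a candidate root bipartition."""

    s_io: float
    s_ad: float
    edge_id: Optional[str] = None


def induced_split(species_tree: SpeciesTree, present: set[str]) -> InOutSplit:
    """Restrict the species tree to ``present`` and split at its deepest node.

    Descends from the species-tree root while all of ``present`` falls within
    a single child; the first node splitting ``present`` into two or more
    non-empty parts defines the out-group (the smallest part; ties broken
    lexicographically — a reporting convention, the scores are symmetric under
    the choice) and the in-group (everything else).
    """
    present = set(present)
    unknown = present - set(species_tree.leaf_set())
    if unknown:
        raise KeyError(f"species not in species tree: {sorted(unknown)}")
    if len(present) < 2:
        raise ValueError("need at least 2 species to induce an in/out split")
    node = species_tree.root
    while True:
        parts = []
        for child in node.children:
            part = present & species_tree.descendant_species(child.node_id)
            if part:
                parts.append(part)
        if len(parts) == 1:
            node = next(c for c in node.children
                        if parts[0] <= species_tree.descendant_species(c.node_id))
            continue
        parts.sort(key=lambda p: (len(p), sorted(p)))
        outgroup = parts[0]
        ingroup = set().union(*parts[1:])
        return InOutSplit(frozenset(outgroup), frozenset(ingroup))


def _score_oriented(O: frozenset, I: frozenset, A: set, B: set) -> tuple[float, float]:
    oa = len(O & A) / len(O)
    ib = len(I & B) / len(I)
    ob = len(O & B) / len(O)
    ia = len(I & A) / len(I)
    return oa * ib * (1.0 - ob) * (1.0 - ia), oa * ib * ob * ia


def score_bipartition(split: InOutSplit, A: set[str], B: set[str]) -> RootScore:
    """Score one gene-tree bipartition with species sets A | B on its sides.

    A and B may overlap (a species can have genes on both sides).  Which side
    is called A is arbitrary, so each score is the maximum over the two
    orientations (S_AD is orientation-symmetric by construction).
    """
    if not A or not B:
        raise ValueError("both sides of a bipartition must contain species")
    io1, ad1 = _score_oriented(split.outgroup, split.ingroup, A, B)
    io2, ad2 = _score_oriented(split.outgroup, split.ingroup, B, A)
    return RootScore(s_io=max(io1, io2), s_ad=max(ad1, ad2))


def _surrogate(split: InOutSplit, A: set, B: set) -> float:
    # smooth fallback used only when every edge scores 0 for both products:
    # same four S_IO factors, summed instead of multiplied.
    O, I = split.outgroup, split.ingroup

    def one(A, B):
        return (len(O & A) / len(O) + len(I & B) / len(I)
                + (1 - len(O & B) / len(O)) + (1 - len(I & A) / len(I)))

    return max(one(A, B), one(B, A))


def candidate_edges(tree: GeneTree):
    """Yield (node, A, B, n_genes_below) for every edge of the basal
    multifurcation representation; the edge is identified by its child node."""
    below: dict[int, Counter] = {}
    for node in tree.root.postorder():
        if node.is_leaf:
            below[id(node)] = Counter({node.species: 1})
        else:
            c = Counter()
            for child in node.children:
                c.update(below[id(child)])
            below[id(node)] = c
    total = below[id(tree.root)]
    n_total = sum(total.values())
    for node in tree.root.postorder():
        if node is tree.root:
            continue
        cnt = below[id(node)]
        A = set(cnt)
        B = {s for s in total if total[s] > cnt.get(s, 0)}
        yield node, A, B, sum(cnt.values()), n_total


def _flip_up(node: TreeNode) -> None:
    """Reverse the parent chain above ``node`` so it becomes a top node."""
    parent = node.parent
    if parent is None:
        return
    parent.remove_child(node)
    edge_len = node.length
    _flip_up(parent)
    node.add_child(parent)
    parent.length = edge_len


def _reroot_at(node: TreeNode) -> TreeNode:
    """Place the root on the edge above ``node``; returns the new root."""
    parent = node.parent
    edge_len = node.length
    parent.remove_child(node)
    _flip_up(parent)
    new_root = TreeNode()
    half = None if edge_len is None else edge_len / 2.0
    node.length = half
    parent_top = parent.suppress_unifurcations()
    parent_top.length = half
    new_root.add_child(node)
    new_root.add_child(parent_top)
    return new_root


def _trivial_root(tree: GeneTree) -> tuple[GeneTree, RootScore]:
    # single-species or 2-leaf trees: root on the longest edge (first
    # post-order edge when branch lengths are absent).
    best = None
    for node in tree.root.postorder():
        if node is tree.root:
            continue
        length = node.length if node.length is not None else 0.0
        if best is None or length > best[0]:
            best = (length, node)
    if best is None:
        raise ValueError("cannot root a single-leaf tree")
    new_root = _reroot_at(best[1])
    assign_node_ids(new_root)
    rooted = GeneTree(root=new_root, rooted=True, labels=tree.labels, name=tree.name)
    return rooted, RootScore(0.0, 0.0, edge_id=best[1].node_id)


def root_gene_tree(
    tree: GeneTree, species_tree: SpeciesTree
) -> tuple[GeneTree, RootScore]:
    """Root an unrooted gene tree on the edge maximising max(S_IO, S_AD).

    Ties are broken towards the edge whose lighter side carries fewer genes,
    then by post-order edge index, so output is deterministic.  Returns the
    rooted tree (same leaf set, fresh node ids) and the winning score.
    """
    work = GeneTree(root=tree.root.copy(), rooted=False,
                    labels=tree.labels, name=tree.name)
    present = work.species()
    if len(present) < 2 or work.n_leaves() == 2:
        return _trivial_root(work)
    split = induced_split(species_tree, present)

    best = None  # (score, tiebreak..., node)
    scored = []
    for idx, (node, A, B, n_below, n_total) in enumerate(candidate_edges(work)):
        rs = score_bipartition(split, A, B)
        key = (-max(rs.s_io, rs.s_ad), min(n_below, n_total - n_below), idx)
        scored.append((key, node, rs, A, B))
        if best is None or key < best[0]:
            best = (key, node, rs)

    if max(best[2].s_io, best[2].s_ad) == 0.0:
        log.warning("%s: all bipartitions score 0 for both S_IO and S_AD; "
                    "falling back to the summed-factor surrogate",
                    tree.name or "<tree>")
        best = None
        for key, node, rs, A, B in scored:
            skey = (-_surrogate(split, A, B), key[1], key[2])
            if best is None or skey < best[0]:
                best = (skey, node, rs)

    _, node, rs = best
    edge_id = node.node_id
    new_root = _reroot_at(node)
    assign_node_ids(new_root)
    rooted = GeneTree(root=new_root, rooted=True, labels=work.labels, name=work.name)
    return rooted, RootScore(rs.s_io, rs.s_ad, edge_id=edge_id)
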