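"""Hybrid species-overlap + duplication-loss-coalescent (DLC) tree resolution.

A node of a rooted gene tree is a *duplication* when the species sets below
its children overlap, otherwise a *speciation* (the species-overlap
criterion).  At a duplication node, a *loss* is charged for each species
present below the node but absent below one of its children.  Gene-tree
inference error and incomplete lineage sorting routinely manufacture spurious
overlaps: a single misplaced gene turns a speciation node into an apparent
duplication with a long tail of phantom losses.

The resolver walks the rooted tree in post-order.  At each duplication node
it examines the clades up to topological depth two below the node (each
child and its children) and asks whether pruning one such clade and
regrafting it as sister to a clade on the other side yields a strictly more
parsimonious interpretation, counting duplications + losses by the same
overlap rules.  If so, the cheapest rearrangement is applied.  Because the
traversal is post-order, descendants are already in their most parsimonious
form when a node is analysed, and rearrangements below a node never disturb
the rest of the traversal.  Passes repeat until no rearrangement fires, so
the output is a fixed point (resolving twice changes nothing).  The result
is the "resolved" gene tree — the locus tree of the DLC model — from which
orthologs and duplication events are read off.

``dlc_oracle`` is an independent brute-force checker: it enumerates the same
depth-2 prune-and-regraft neighbourhood on whole-tree copies with a separate
naive cost count and reports all minimal-cost topologies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .tree_io import GeneTree, TreeNode, assign_node_ids

__all__ = [
    "NodeAnnotation",
    "SubCase",
    "Rearrangement",
    "ResolvedTree",
    "annotate_overlap",
    "dl_cost",
    "classify_subcase",
    "resolve_tree",
    "dlc_oracle",
    "canonical_topology",
]


# ---------------------------------------------------------------------------
# species-overlap annotation and DL cost
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NodeAnnotation:
    node_id: Optional[str]
    species_below: frozenset[str]
    event: str  # "leaf" | "speciation" | "duplication"
    losses: int


def _species_sets(root: TreeNode) -> dict[int, frozenset[str]]:
    sets: dict[int, frozenset[str]] = {}
    for node in root.postorder():
        if node.is_leaf:
            sets[id(node)] = frozenset((node.species,))
        else:
            acc: set[str] = set()
            for child in node.children:
                acc |= sets[id(child)]
            sets[id(node)] = frozenset(acc)
    return sets


def _is_duplication(node: TreeNode, sets: dict[int, frozenset[str]]) -> bool:
    child_sets = [sets[id(c)] for c in node.children]
    for i in range(len(child_sets)):
        for j in range(i + 1, len(child_sets)):
            if child_sets[i] & child_sets[j]:
                return True
    return False


def annotate_overlap(tree: GeneTree | TreeNode) -> dict[int, NodeAnnotation]:
    """Annotate every node with its species set, event type and loss count.

    Losses are counted at duplication nodes only: one loss per (child,
    species) pair where the species occurs below the node but not below that
    child.  Keyed by ``id(node)``.
    """
    root = tree.root if isinstance(tree, GeneTree) else tree
    sets = _species_sets(root)
    out: dict[int, NodeAnnotation] = {}
    for node in root.postorder():
        if node.is_leaf:
            out[id(node)] = NodeAnnotation(node.node_id, sets[id(node)], "leaf", 0)
            continue
        if _is_duplication(node, sets):
            losses = sum(len(sets[id(node)] - sets[id(c)]) for c in node.children)
            out[id(node)] = NodeAnnotation(
                node.node_id, sets[id(node)], "duplication", losses)
        else:
            out[id(node)] = NodeAnnotation(
                node.node_id, sets[id(node)], "speciation", 0)
    return out


def dl_cost(root: TreeNode) -> int:
    """Duplications + losses in the subtree, by the overlap criteria."""
    sets = _species_sets(root)
    cost = 0
    for node in root.postorder():
        if node.is_leaf:
            continue
        if _is_duplication(node, sets):
            cost += 1 + sum(len(sets[id(node)] - sets[id(c)]) for c in node.children)
    return cost


def canonical_topology(root: TreeNode) -> str:
    """Order-independent Newick-like signature of a (sub)tree topology."""

    def rec(node: TreeNode) -> str:
        if node.is_leaf:
            return node.label
        return "(" + ",".join(sorted(rec(c) for c in node.children)) + ")"

    return rec(root) + ";"


# ---------------------------------------------------------------------------
# depth-2 prune-and-regraft neighbourhood
# ---------------------------------------------------------------------------

def _depth2_clades(child: TreeNode) -> list[TreeNode]:
    # the child itself plus its children: total topological depth <= 2
    # below the node being analysed.
    return [child] + list(child.children)


def _enumerate_moves(left: TreeNode, right: TreeNode):
    """(prune X, regraft target Y) pairs across the two sides.

    Pruning a whole child and regrafting it as sister to the whole other
    child reproduces the input topology, so those two pairs are skipped.
    """
    for src, dst in ((left, right), (right, left)):
        for X in _depth2_clades(src):
            for Y in _depth2_clades(dst):
                if X is src and Y is dst:
                    continue
                yield X, Y


def _copy_with_map(node: TreeNode, mapping: dict[int, TreeNode]) -> TreeNode:
    clone = TreeNode(node.label, node.length)
    clone.species = node.species
    clone.node_id = node.node_id
    mapping[id(node)] = clone
    for child in node.children:
        clone.add_child(_copy_with_map(child, mapping))
    return clone


def _splice_unary(node: TreeNode) -> TreeNode:
    """Splice out ``node`` if it has exactly one child; returns its
    replacement (the child) or ``node`` unchanged."""
    if node.is_leaf or len(node.children) != 1:
        return node
    child = node.children[0]
    parent = node.parent
    child.parent = parent
    if parent is not None:
        parent.children[parent.children.index(node)] = child
    if node.length is not None and child.length is not None:
        child.length += node.length
    node.children = []
    node.parent = None
    return child


def _apply_move(v: TreeNode, X: TreeNode, Y: TreeNode) -> TreeNode:
    """Prune X, regraft as sister of Y; suppresses the unifurcation the
    prune leaves behind.  Returns the replacement of ``v`` (a different node
    only when ``v`` itself was the pruned clade's parent and got spliced)."""
    q = X.parent
    X.detach()
    parent = Y.parent
    idx = parent.children.index(Y)
    joint = TreeNode()
    parent.children[idx] = joint
    joint.parent = parent
    Y.parent = joint
    joint.children.append(Y)
    joint.add_child(X)
    replacement = _splice_unary(q)
    return replacement if q is v else v


def _n_genes(node: TreeNode) -> int:
    return sum(1 for _ in node.leaves())


# ---------------------------------------------------------------------------
# sub-case classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubCase:
    """Classification of one duplication node.

    ``pattern`` records, per side, where the smallest clade containing the
    full overlapping species set sits ("child", "grandchild-0", ...).
    ``action`` is "keep" or "regraft"; a regraft always strictly lowers the
    local duplication+loss cost.
    """

    pattern: tuple[str, str]
    action: str
    dl_cost_before: int
    dl_cost_after: int
    move: Optional[tuple[TreeNode, TreeNode]] = None  # (prune X, target Y)


def _overlap_position(child: TreeNode, overlap: frozenset[str],
                      sets: dict[int, frozenset[str]]) -> str:
    """Position of the smallest depth<=2 clade containing the overlap set."""
    best = "child"
    best_size = len(sets[id(child)])
    for i, g in enumerate(child.children):
        gset = sets[id(g)]
        if overlap <= gset and len(gset) < best_size:
            best, best_size = f"grandchild-{i}", len(gset)
    return best


def classify_subcase(v: TreeNode, left: TreeNode, right: TreeNode) -> SubCase:
    """Classify a duplication node (w.r.t. the child pair left/right) and
    pick its most parsimonious interpretation.

    Every depth-2 prune-and-regraft neighbour is costed with ``dl_cost``;
    the cheapest strictly-improving rearrangement wins.  Ties between "keep"
    and a rearrangement resolve to "keep"; ties among rearrangements resolve
    to the move relocating fewer genes, then to enumeration order.
    """
    sets = _species_sets(v)
    overlap = sets[id(left)] & sets[id(right)]
    pattern = (_overlap_position(left, overlap, sets),
               _overlap_position(right, overlap, sets))
    cost_keep = dl_cost(v)

    best: Optional[tuple[tuple[int, int, int], TreeNode, TreeNode, int]] = None
    for mi, (X, Y) in enumerate(_enumerate_moves(left, right)):
        mapping: dict[int, TreeNode] = {}
        trial_v = _copy_with_map(v, mapping)
        trial = _apply_move(trial_v, mapping[id(X)], mapping[id(Y)])
        cost = dl_cost(trial)
        key = (cost, _n_genes(X), mi)
        if best is None or key < best[0]:
            best = (key, X, Y, cost)

    if best is not None and best[3] < cost_keep:
        return SubCase(pattern, "regraft", cost_keep, best[3], (best[1], best[2]))
    return SubCase(pattern, "keep", cost_keep, cost_keep, None)


# ---------------------------------------------------------------------------
# the resolver
# ---------------------------------------------------------------------------

@dataclass
class Rearrangement:
    """Provenance of one applied rearrangement."""

    node_id: Optional[str]
    node_leaves: tuple[str, ...]  # leaf labels below the analysed node
    pattern: tuple[str, str]
    action: str
    dl_cost_before: int
    dl_cost_after: int
    tree_before: Optional[str] = None  # whole-tree canonical topology (trace)
    tree_after: Optional[str] = None


@dataclass
class ResolvedTree:
    """A rooted gene tree after resolution, with its rearrangement log."""

    tree: GeneTree
    provenance: list[Rearrangement] = field(default_factory=list)


def _handle_node(v: TreeNode, tree_root_ref: list[TreeNode],
                 prov: list[Rearrangement], trace: bool) -> TreeNode:
    """Resolve duplications at a single node; returns v's replacement."""
    while True:
        if v.is_leaf or len(v.children) < 2:
            return v
        sets = _species_sets(v)
        pairs = []
        kids = v.children
        for i in range(len(kids)):
            for j in range(i + 1, len(kids)):
                ov = sets[id(kids[i])] & sets[id(kids[j])]
                if ov:
                    pairs.append((-len(ov), i, j))
        pairs.sort()
        applied = False
        for _, i, j in pairs:
            sub = classify_subcase(v, kids[i], kids[j])
            if sub.action == "keep":
                continue
            before = canonical_topology(tree_root_ref[0]) if trace else None
            X, Y = sub.move
            record = Rearrangement(
                node_id=v.node_id,
                node_leaves=tuple(sorted(v.leaf_labels())),
                pattern=sub.pattern,
                action=sub.action,
                dl_cost_before=sub.dl_cost_before,
                dl_cost_after=sub.dl_cost_after,
                tree_before=before,
            )
            was_root = tree_root_ref[0] is v
            replacement = _apply_move(v, X, Y)
            if replacement is not v and was_root:
                tree_root_ref[0] = replacement
            if trace:
                record.tree_after = canonical_topology(tree_root_ref[0])
            prov.append(record)
            v = replacement
            applied = True
            break
        if not applied:
            return v


def _resolve_pass(node: TreeNode, tree_root_ref: list[TreeNode],
                  prov: list[Rearrangement], trace: bool) -> TreeNode:
    if node.is_leaf:
        return node
    for i in range(len(node.children)):
        child = node.children[i]
        new_child = _resolve_pass(child, tree_root_ref, prov, trace)
        if new_child is not child:
            node.children[i] = new_child
            new_child.parent = node
    return _handle_node(node, tree_root_ref, prov, trace)


def resolve_tree(tree: GeneTree, trace: bool = False) -> ResolvedTree:
    """Resolve a rooted gene tree to its most parsimonious local form.

    Post-order passes run until no duplication node admits a strictly
    cheaper depth-2 rearrangement (total cost strictly decreases with every
    applied move, so this terminates; almost all trees converge in one
    pass).  The leaf multiset is conserved.  With ``trace=True`` each
    provenance record also carries whole-tree topologies before/after the
    move, which the brute-force oracle tests consume.
    """
    if not tree.rooted:
        raise ValueError("resolve_tree requires a rooted gene tree")
    work = GeneTree(root=tree.root.copy(), rooted=True,
                    labels=tree.labels, name=tree.name)
    prov: list[Rearrangement] = []
    root_ref = [work.root]
    while True:
        n_before = len(prov)
        new_root = _resolve_pass(root_ref[0], root_ref, prov, trace)
        root_ref[0] = new_root
        if len(prov) == n_before:
            break
    work.root = root_ref[0]
    assign_node_ids(work.root)
    return ResolvedTree(tree=work, provenance=prov)


# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------

def _naive_cost(root: TreeNode) -> int:
    """Independent duplication+loss count (recursive, no shared helpers)."""

    def leafset(n: TreeNode) -> set[str]:
        if n.is_leaf:
            return {n.species}
        out: set[str] = set()
        for c in n.children:
            out |= leafset(c)
        return out

    def rec(n: TreeNode) -> int:
        if n.is_leaf:
            return 0
        total = sum(rec(c) for c in n.children)
        css = [leafset(c) for c in n.children]
        dup = any(css[i] & css[j]
                  for i in range(len(css)) for j in range(i + 1, len(css)))
        if dup:
            union = set().union(*css)
            total += 1 + sum(len(union - cs) for cs in css)
        return total

    return rec(root)


def dlc_oracle(tree: GeneTree, node_leaves: Optional[set[str]] = None,
               max_leaves: int = 12) -> dict[frozenset, tuple[int, set[str]]]:
    """Exhaustive depth-2 neighbourhood search around duplication nodes.

    For each duplication node (or only the node whose leaf-label set equals
    ``node_leaves``), applies every prune-and-regraft move within depth two
    below the node to a copy of the *whole* tree, recomputes the total
    duplication+loss cost from scratch, and returns, keyed by the node's
    leaf-label set, the minimal cost and the set of canonical whole-tree
    topologies achieving it (the unchanged tree is always a candidate).
    """
    root = tree.root if isinstance(tree, GeneTree) else tree
    if sum(1 for _ in root.leaves()) > max_leaves:
        raise ValueError(f"oracle refuses trees with more than {max_leaves} leaves")
    sets = _species_sets(root)
    results: dict[frozenset, tuple[int, set[str]]] = {}
    for node in root.postorder():
        if node.is_leaf or not _is_duplication(node, sets):
            continue
        leaves_here = frozenset(node.leaf_labels())
        if node_leaves is not None and leaves_here != frozenset(node_leaves):
            continue
        candidates: dict[str, int] = {canonical_topology(root): _naive_cost(root)}
        kids = node.children
        for i in range(len(kids)):
            for j in range(i + 1, len(kids)):
                if not (sets[id(kids[i])] & sets[id(kids[j])]):
                    continue
                for X, Y in _enumerate_moves(kids[i], kids[j]):
                    mapping: dict[int, TreeNode] = {}
                    copy_root = _copy_with_map(root, mapping)
                    v_copy = mapping[id(node)]
                    repl = _apply_move(v_copy, mapping[id(X)], mapping[id(Y)])
                    whole = repl if (v_copy is copy_root and repl is not v_copy) else copy_root
                    candidates[canonical_topology(whole)] = _naive_cost(whole)
        min_cost = min(candidates.values())
        results[leaves_here] = (
            min_cost,
            {topo for topo, c in candidates.items() if c == min_cost},
        )
    return results
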