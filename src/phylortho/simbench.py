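"""Simulation of gene families with known duplication history, and the
exact-match duplication benchmark.

The generator runs a birth–death process along a rooted species tree: one
gene enters the species-tree root, duplications arise on each branch as a
Poisson process at rate ``dup_rate`` per lineage per unit branch length,
losses prune lineages at rate ``loss_rate``, and surviving lineages split
at each species-tree node.  Every duplication whose both copies leave
surviving descendants is recorded as a ground-truth event — the unordered
pair of the two post-duplication gene sets — and ground-truth orthologs are
the cross-species gene pairs whose divergence node is a speciation.
Gene-tree inference error is emulated by applying ``nni_moves`` random
nearest-neighbour-interchange moves to the true tree before handing it,
unrooted, to the inference pipeline.

Scoring follows the exact-match criterion: an inferred duplication is
correct iff its two post-duplication gene sets equal a ground-truth event's
two sets exactly.  Precision, recall and F-score are reported per method
(pure species overlap vs. the hybrid resolver) over a pooled set of
families.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from . import orthology, rooting
from .orthology import DuplicationEvent, OrthologRelation
from .resolver import resolve_tree
from .tree_io import GeneTree, SpeciesTree, TreeNode, assign_node_ids, write_tree

__all__ = [
    "SimulationConfig",
    "TrueDuplication",
    "GroundTruth",
    "default_species_tree",
    "simulate_family",
    "simulate_dataset",
    "emit_dataset",
    "score_duplications",
    "ortholog_pairs",
    "benchmark",
]


class RunawayFamilyError(ValueError):
    """The configured rates imply unmanageably large families."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated dataset.

    Defaults model a flies-like study: 12 species, 500 families, a
    duplication rate giving on the order of one duplication per family, no
    losses and no topological noise (both are switched on per experiment).
    """

    species_tree: SpeciesTree
    dup_rate: float = 0.05      # events / lineage / unit branch length
    loss_rate: float = 0.0
    n_families: int = 500
    nni_moves: int = 0
    seed: int = 0
    size_cap: int = 10_000      # cap on the *expected* family size
    max_redraws: int = 1000

    def __post_init__(self):
        if self.dup_rate < 0 or self.loss_rate < 0:
            raise ValueError("rates must be non-negative")
        if self.nni_moves < 0:
            raise ValueError("nni_moves must be a non-negative integer")


@dataclass(frozen=True)
class TrueDuplication:
    branch_id: str
    post_dup_sets: tuple[frozenset[str], frozenset[str]]


@dataclass
class GroundTruth:
    """Per-family truth: the rooted true tree, the observed duplication
    events, and the complete cross-species ortholog pair set."""

    family_id: str
    tree: GeneTree
    events: list[TrueDuplication] = field(default_factory=list)
    ortholog_pairs: set[frozenset[str]] = field(default_factory=set)


def default_species_tree(n_species: int = 12) -> SpeciesTree:
    """A balanced rooted species tree over s01..sNN with unit branch lengths."""
    if n_species < 2:
        raise ValueError("need at least 2 species")
    names = [f"s{i + 1:02d}" for i in range(n_species)]

    def build(labels: list[str]) -> TreeNode:
        if len(labels) == 1:
            node = TreeNode(label=labels[0], length=1.0)
            node.species = labels[0]
            return node
        mid = (len(labels) + 1) // 2
        node = TreeNode(length=1.0)
        node.add_child(build(labels[:mid]))
        node.add_child(build(labels[mid:]))
        return node

    root = build(names)
    root.length = None
    return SpeciesTree(root=root)


# ---------------------------------------------------------------------------
# birth-death simulation along the species tree
# ---------------------------------------------------------------------------

def _check_rates(config: SimulationConfig) -> None:
    depth: dict[int, float] = {}
    max_depth = 0.0
    for node in config.species_tree.root.preorder():
        if node.parent is None:
            depth[id(node)] = 0.0
            continue
        d = depth[id(node.parent)] + (node.length if node.length is not None else 1.0)
        depth[id(node)] = d
        if node.is_leaf:
            max_depth = max(max_depth, d)
    n = len(config.species_tree.leaf_set())
    expected = n * float(np.exp((config.dup_rate - config.loss_rate) * max_depth))
    if expected > config.size_cap:
        raise RunawayFamilyError(
            f"expected family size {expected:.0f} exceeds cap {config.size_cap}; "
            "lower the duplication rate or raise size_cap")


def _simulate_tree(config: SimulationConfig, family_id: str, rng):
    """One family draw; returns (root TreeNode or None, events dict, counters)."""
    lam, mu = config.dup_rate, config.loss_rate
    total_rate = lam + mu
    events: dict[int, tuple[str, str]] = {}   # id(node) -> (kind, branch_id)
    counters: dict[str, int] = {}

    def new_leaf(sp: str) -> TreeNode:
        k = counters.get(sp, 0) + 1
        counters[sp] = k
        leaf = TreeNode(label=f"{sp}_{family_id}g{k}")
        leaf.species = sp
        return leaf

    def at_node(sp_node: TreeNode) -> Optional[TreeNode]:
        if sp_node.is_leaf:
            return new_leaf(sp_node.label)
        subs = [evolve(c.length if c.length is not None else 1.0, c)
                for c in sp_node.children]
        alive = [s for s in subs if s is not None]
        if not alive:
            return None
        if len(alive) == 1:
            return alive[0]
        node = TreeNode()
        for s in alive:
            node.add_child(s)
        events[id(node)] = ("speciation", sp_node.node_id)
        return node

    def evolve(t_remaining: float, sp_child: TreeNode) -> Optional[TreeNode]:
        while True:
            wait = rng.exponential(1.0 / total_rate) if total_rate > 0 else np.inf
            if wait >= t_remaining:
                return at_node(sp_child)
            t_remaining -= wait
            if rng.random() < (mu / total_rate):
                return None  # loss
            first = evolve(t_remaining, sp_child)
            second = evolve(t_remaining, sp_child)
            if first is None and second is None:
                return None
            if first is None or second is None:
                return first if second is None else second
            node = TreeNode()
            node.add_child(first)
            node.add_child(second)
            events[id(node)] = ("duplication", sp_child.node_id)
            return node

    root = at_node(config.species_tree.root)
    return root, events


def _collect_truth(family_id: str, root: TreeNode,
                   events: dict[int, tuple[str, str]]) -> GroundTruth:
    leafsets: dict[int, frozenset[str]] = {}
    for node in root.postorder():
        if node.is_leaf:
            leafsets[id(node)] = frozenset((node.label,))
        else:
            leafsets[id(node)] = frozenset().union(
                *(leafsets[id(c)] for c in node.children))
    truth_events: list[TrueDuplication] = []
    pairs: set[frozenset[str]] = set()
    for node in root.postorder():
        if node.is_leaf:
            continue
        kind, branch = events[id(node)]
        if kind == "duplication":
            truth_events.append(TrueDuplication(
                branch_id=branch,
                post_dup_sets=(leafsets[id(node.children[0])],
                               leafsets[id(node.children[1])]),
            ))
        else:
            left, right = node.children
            for gl in left.leaves():
                for gr in right.leaves():
                    if gl.species != gr.species:
                        pairs.add(frozenset((gl.label, gr.label)))
    labels = {l.label: None for l in root.leaves()}
    tree = GeneTree(root=root, rooted=True, labels=labels, name=family_id)
    assign_node_ids(tree.root)
    return GroundTruth(family_id=family_id, tree=tree,
                       events=truth_events, ortholog_pairs=pairs)


def _nni(root: TreeNode, rng) -> None:
    """One random nearest-neighbour interchange in place."""
    cands = [n for n in root.preorder()
             if n.parent is not None and not n.is_leaf]
    if not cands:
        return
    v = cands[int(rng.integers(len(cands)))]
    p = v.parent
    sibs = [c for c in p.children if c is not v]
    s = sibs[int(rng.integers(len(sibs)))]
    c = v.children[int(rng.integers(len(v.children)))]
    iv, ip = v.children.index(c), p.children.index(s)
    v.children[iv], s.parent = s, v
    p.children[ip], c.parent = c, p


def _as_unrooted(tree: GeneTree) -> GeneTree:
    root = tree.root.copy()
    if len(root.children) == 2 and sum(1 for _ in root.leaves()) > 2:
        keep, merge = root.children
        if merge.is_leaf:
            keep, merge = merge, keep
        if not merge.is_leaf:
            root.remove_child(merge)
            for child in list(merge.children):
                merge.remove_child(child)
                root.add_child(child)
    root = root.suppress_unifurcations()
    assign_node_ids(root)
    return GeneTree(root=root, rooted=False, labels=dict(tree.labels),
                    name=tree.name)


def simulate_family(
    config: SimulationConfig, family_id: str, rng=None
) -> tuple[GeneTree, GroundTruth]:
    """Simulate one family; returns (noisy unrooted gene tree, ground truth).

    Families with fewer than two surviving genes are discarded and redrawn
    (up to ``max_redraws`` attempts).  With ``nni_moves`` = 0 the returned
    tree is the true tree, merely unrooted.
    """
    _check_rates(config)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    for _ in range(config.max_redraws):
        root, events = _simulate_tree(config, family_id, rng)
        if root is not None and sum(1 for _ in root.leaves()) >= 2:
            break
    else:
        raise RuntimeError(
            f"failed to draw a surviving family in {config.max_redraws} attempts")
    truth = _collect_truth(family_id, root, events)
    noisy = _as_unrooted(truth.tree)
    for _ in range(config.nni_moves):
        _nni(noisy.root, rng)
    assign_node_ids(noisy.root)
    return noisy, truth


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[list[GeneTree], list[GroundTruth]]:
    """Simulate ``n_families`` families from one seeded stream."""
    rng = np.random.default_rng(config.seed)
    trees, truths = [], []
    for i in range(config.n_families):
        tree, truth = simulate_family(config, f"F{i:04d}", rng)
        trees.append(tree)
        truths.append(truth)
    return trees, truths


def emit_dataset(config: SimulationConfig, outdir) -> None:
    """Write a simulated dataset in the pipeline's input layout:
    one Newick file per family, the species tree, and truth TSVs."""
    outdir = Path(outdir)
    (outdir / "trees").mkdir(parents=True, exist_ok=True)
    trees, truths = simulate_dataset(config)
    (outdir / "species_tree.nwk").write_text(write_tree(config.species_tree))
    for tree in trees:
        (outdir / "trees" / f"{tree.name}.nwk").write_text(write_tree(tree))
    ev_rows = [
        {"orthogroup": t.family_id,
         "species_tree_branch": e.branch_id,
         "genes_1": ",".join(sorted(e.post_dup_sets[0])),
         "genes_2": ",".join(sorted(e.post_dup_sets[1]))}
        for t in truths for e in t.events
    ]
    pd.DataFrame(ev_rows, columns=["orthogroup", "species_tree_branch",
                                   "genes_1", "genes_2"]).to_csv(
        outdir / "true_duplications.tsv", sep="\t", index=False)
    pair_rows = [
        {"orthogroup": t.family_id, "gene_1": a, "gene_2": b}
        for t in truths
        for a, b in sorted(tuple(sorted(p)) for p in t.ortholog_pairs)
    ]
    pd.DataFrame(pair_rows, columns=["orthogroup", "gene_1", "gene_2"]).to_csv(
        outdir / "true_orthologs.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def _event_key(family: Optional[str],
               sets: tuple[frozenset[str], frozenset[str]]):
    return (family, frozenset((sets[0], sets[1])))


def score_duplications(
    inferred: Iterable[DuplicationEvent],
    truths: Iterable[GroundTruth],
) -> tuple[float, float, float]:
    """Exact-match precision/recall/F over pooled families.

    A true positive is an inferred event whose unordered pair of
    post-duplication gene sets equals a ground-truth event's pair exactly;
    each truth event can be matched at most once.  F is 0 when both counts
    are 0-divisions.
    """
    truth_keys: dict = {}
    n_truth = 0
    for t in truths:
        for e in t.events:
            truth_keys[_event_key(t.family_id, e.post_dup_sets)] = (
                truth_keys.get(_event_key(t.family_id, e.post_dup_sets), 0) + 1)
            n_truth += 1
    tp = 0
    n_inferred = 0
    for ev in inferred:
        n_inferred += 1
        key = _event_key(ev.orthogroup, ev.post_dup_sets)
        if truth_keys.get(key, 0) > 0:
            truth_keys[key] -= 1
            tp += 1
    precision = tp / n_inferred if n_inferred else 0.0
    recall = tp / n_truth if n_truth else 0.0
    f = (2 * precision * recall / (precision + recall)
         if (precision + recall) > 0 else 0.0)
    return precision, recall, f


def ortholog_pairs(relations: Iterable[OrthologRelation]) -> set[frozenset[str]]:
    """Expand grouped relations into the set of individual gene pairs."""
    pairs: set[frozenset[str]] = set()
    for rel in relations:
        for a in rel.genes_left:
            for b in rel.genes_right:
                pairs.add(frozenset((a, b)))
    return pairs


def infer_events(
    trees: Iterable[GeneTree],
    species_tree: SpeciesTree,
    resolve: bool = True,
) -> list[DuplicationEvent]:
    """Run rooting (+ optional resolution) and extract duplication events."""
    out: list[DuplicationEvent] = []
    for tree in trees:
        rooted, _ = rooting.root_gene_tree(tree, species_tree)
        final = resolve_tree(rooted).tree if resolve else rooted
        out.extend(orthology.extract_duplications(final, species_tree))
    return out


def benchmark(
    config: SimulationConfig,
    methods: tuple[str, ...] = ("overlap", "hybrid"),
) -> pd.DataFrame:
    """Score the pure species-overlap pipeline against the hybrid resolver
    on one simulated dataset; identical inputs for both methods."""
    trees, truths = simulate_dataset(config)
    rows = []
    for method in methods:
        events = infer_events(trees, config.species_tree,
                              resolve=(method == "hybrid"))
        p, r, f = score_duplications(events, truths)
        rows.append({"method": method, "precision": p, "recall": r,
                     "f_score": f, "n_inferred": len(events),
                     "n_true": sum(len(t.events) for t in truths)})
    return pd.DataFrame(rows, columns=["method", "precision", "recall",
                                       "f_score", "n_inferred", "n_true"])
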