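"""Species-overlap annotation, DL cost, and the hybrid resolver."""

import numpy as np
import pytest

from phylortho.resolver import (
    annotate_overlap,
    canonical_topology,
    classify_subcase,
    dl_cost,
    dlc_oracle,
    resolve_tree,
)
from phylortho.tree_io import GeneTree, read_rooted_gene_tree

from conftest import random_gene_tree


def rooted(nwk: str) -> GeneTree:
    return read_rooted_gene_tree(nwk)


class TestAnnotateOverlap:
    def test_speciation_node(self):
        tree = rooted("((A_1,B_1),C_1);")
        ann = annotate_overlap(tree)
        root = ann[id(tree.root)]
        assert root.event == "speciation"
        assert root.losses == 0

    def test_duplication_with_losses(self):
        # children span {A,B} and {B,C}: duplication, A and C each lost once
        tree = rooted("((A_1,B_1),(B_2,C_1));")
        ann = annotate_overlap(tree)
        root = ann[id(tree.root)]
        assert root.event == "duplication"
        assert root.losses == 2

    def test_terminal_duplication(self):
        tree = rooted("((A_1,A_2),B_1);")
        ann = annotate_overlap(tree)
        cherry = next(n for n in tree.root.postorder()
                      if not n.is_leaf and n is not tree.root)
        assert ann[id(cherry)].event == "duplication"
        assert ann[id(cherry)].losses == 0

    def test_species_below_is_union_of_children(self):
        tree = rooted("(((A_1,B_1),C_1),(B_2,D_1));")
        ann = annotate_overlap(tree)
        for node in tree.root.postorder():
            if node.is_leaf:
                continue
            union = frozenset().union(
                *(ann[id(c)].species_below for c in node.children))
            assert ann[id(node)].species_below == union


class TestDlCost:
    def test_clean_duplication_costs_one(self):
        assert dl_cost(rooted("((A_1,B_1),(A_2,B_2));").root) == 1

    def test_duplication_plus_loss(self):
        assert dl_cost(rooted("((A_1,B_1),B_2);").root) == 2

    def test_speciation_ladder_costs_zero(self):
        assert dl_cost(rooted("(((A_1,B_1),C_1),D_1);").root) == 0

    def test_nested(self):
        # root dup over {A,B,C}|{C,D}: 1 dup + losses(D; A,B) = 4
        assert dl_cost(rooted("(((A_1,B_1),C_1),(C_2,D_1));").root) == 4


class TestClassifySubcase:
    def test_regraft_identified(self):
        tree = rooted("(((A_1,B_1),C_1),(C_2,D_1));")
        left, right = tree.root.children
        sub = classify_subcase(tree.root, left, right)
        assert sub.action == "regraft"
        assert sub.dl_cost_after < sub.dl_cost_before
        assert sub.pattern == ("grandchild-1", "grandchild-0")

    def test_keep_for_full_duplication(self):
        tree = rooted("((A_1,B_1),(A_2,B_2));")
        left, right = tree.root.children
        sub = classify_subcase(tree.root, left, right)
        assert sub.action == "keep"
        assert sub.dl_cost_before == sub.dl_cost_after == 1

    def test_leaf_child_candidate_is_leaf(self):
        tree = rooted("(A_1,(A_2,B_1));")
        left, right = tree.root.children
        sub = classify_subcase(tree.root, left, right)
        assert sub.pattern[0] == "child"  # the leaf itself


class TestResolveTree:
    def test_spurious_duplication_repaired(self):
        # two topologies are equally parsimonious under the overlap-based
        # cost (the restored C-cherry can sit on either side of the C/D
        # split); both give identical orthologs and the same C-branch event
        tree = rooted("(((A_1,B_1),C_1),(C_2,D_1));")
        res = resolve_tree(tree)
        minima = {
            canonical_topology(rooted("(((A_1,B_1),(C_1,C_2)),D_1);").root),
            canonical_topology(rooted("((A_1,B_1),((C_1,C_2),D_1));").root),
        }
        assert canonical_topology(res.tree.root) in minima
        assert len(res.provenance) == 1
        rec = res.provenance[0]
        assert rec.dl_cost_before == 4 and rec.dl_cost_after == 1

    def test_no_duplications_unchanged(self):
        tree = rooted("(((A_1,B_1),C_1),D_1);")
        res = resolve_tree(tree)
        assert res.provenance == []
        assert canonical_topology(res.tree.root) == canonical_topology(tree.root)

    def test_perfect_family_duplication_kept(self):
        tree = rooted("(((A_1,B_1),C_1),((A_2,B_2),C_2));")
        res = resolve_tree(tree)
        assert res.provenance == []
        assert canonical_topology(res.tree.root) == canonical_topology(tree.root)

    def test_requires_rooted(self):
        tree = rooted("((A_1,B_1),C_1);")
        tree.rooted = False
        with pytest.raises(ValueError):
            resolve_tree(tree)

    @pytest.mark.parametrize("seed", range(40))
    def test_leafset_conserved_cost_monotone_idempotent(self, seed):
        rng = np.random.default_rng(1000 + seed)
        tree = random_gene_tree(rng, int(rng.integers(4, 16)),
                                ["A", "B", "C", "D", "E"])
        res = resolve_tree(tree)
        assert sorted(res.tree.root.leaf_labels()) == \
            sorted(tree.root.leaf_labels())
        assert dl_cost(res.tree.root) <= dl_cost(tree.root)
        for rec in res.provenance:
            assert rec.dl_cost_after < rec.dl_cost_before
        again = resolve_tree(res.tree)
        assert again.provenance == []
        assert canonical_topology(again.tree.root) == \
            canonical_topology(res.tree.root)

    def test_multifurcating_duplication_resolved_pairwise(self):
        tree = rooted("((A_1,B_1),C_1,(C_2,D_1));")
        res = resolve_tree(tree)
        assert sorted(res.tree.root.leaf_labels()) == \
            sorted(["A_1", "B_1", "C_1", "C_2", "D_1"])
        assert dl_cost(res.tree.root) <= dl_cost(tree.root)


class TestDlcOracle:
    def test_minimal_set_on_regraft_example(self):
        tree = rooted("(((A_1,B_1),C_1),(C_2,D_1));")
        result = dlc_oracle(tree)
        leaves = frozenset(tree.root.leaf_labels())
        min_cost, topologies = result[leaves]
        assert min_cost == 1
        # every minimal topology restores the (C_1,C_2) cherry; the cherry's
        # attachment side is cost-neutral under the overlap-based count
        assert topologies == {
            canonical_topology(rooted("(((A_1,B_1),(C_1,C_2)),D_1);").root),
            canonical_topology(rooted("((A_1,B_1),((C_1,C_2),D_1));").root),
        }

    def test_speciation_only_tree_has_no_entries(self):
        tree = rooted("(((A_1,B_1),C_1),D_1);")
        assert dlc_oracle(tree) == {}

    def test_symmetric_duplication_keep_among_minima(self):
        tree = rooted("(((A_1,B_1),C_1),((A_2,B_2),C_2));")
        result = dlc_oracle(tree)
        leaves = frozenset(tree.root.leaf_labels())
        min_cost, topologies = result[leaves]
        assert canonical_topology(tree.root) in topologies
        assert min_cost == 1

    def test_refuses_large_trees(self):
        rng = np.random.default_rng(0)
        tree = random_gene_tree(rng, 20, ["A", "B"])
        with pytest.raises(ValueError):
            dlc_oracle(tree)
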