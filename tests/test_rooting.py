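"""Gene-tree rooting: induced splits, bipartition scores, root choice."""

from fractions import Fraction

import numpy as np
import pytest

from phylortho.rooting import (
    InOutSplit,
    candidate_edges,
    induced_split,
    root_gene_tree,
    score_bipartition,
)
from phylortho.tree_io import (
    GeneTree,
    assign_node_ids,
    read_gene_tree,
    read_species_tree,
)

from conftest import join, make_leaf, random_rooted_topology


def brute_force_induced_split(species_tree, present):
    """Independent oracle: prune the species tree to ``present`` (rebuild it
    from leaf sets), then read the split at the pruned root."""
    def restrict(node):
        kept = [restrict(c) for c in node.children]
        kept = [k for k in kept if k is not None]
        if node.is_leaf:
            return frozenset({node.label}) if node.label in present else None
        if not kept:
            return None
        if len(kept) == 1:
            return kept[0]
        return tuple(kept)

    reduced = restrict(species_tree.root)
    # chains collapse in restrict(), so the result is the deepest splitting node
    assert isinstance(reduced, tuple), "fewer than 2 present species"

    def flatten(x):
        if isinstance(x, frozenset):
            return x
        out = frozenset()
        for part in x:
            out |= flatten(part)
        return out

    parts = sorted((flatten(p) for p in reduced), key=lambda p: (len(p), sorted(p)))
    return parts[0], frozenset().union(*parts[1:])


class TestInducedSplit:
    def test_root_split(self, simple_species_tree):
        split = induced_split(simple_species_tree, {"x", "y", "o"})
        assert split.outgroup == {"o"}
        assert split.ingroup == {"x", "y"}

    def test_descend_rule(self, simple_species_tree):
        # only the in-group clade is present: descend into (x,y)
        split = induced_split(simple_species_tree, {"x", "y"})
        assert {split.outgroup, split.ingroup} == {frozenset({"x"}),
                                                   frozenset({"y"})}

    def test_partial_presence(self):
        sp = read_species_tree("((A,(B,C)),(D,E));")
        split = induced_split(sp, {"B", "C", "D"})
        assert split.outgroup == {"D"}
        assert split.ingroup == {"B", "C"}

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_brute_force_restriction(self, seed):
        rng = np.random.default_rng(seed)
        sp = read_species_tree("(((A,(B,C)),((D,E),F)),((G,H),(I,J)));")
        pool = sorted(sp.leaf_set())
        k = int(rng.integers(2, len(pool) + 1))
        present = set(rng.choice(pool, size=k, replace=False).tolist())
        split = induced_split(sp, present)
        o_expect, i_expect = brute_force_induced_split(sp, present)
        assert split.outgroup == o_expect
        assert split.ingroup == i_expect

    def test_single_species_rejected(self, simple_species_tree):
        with pytest.raises(ValueError):
            induced_split(simple_species_tree, {"x"})


def direct_products(O, I, A, B):
    """The two printed score products, evaluated with exact arithmetic."""
    O, I, A, B = map(frozenset, (O, I, A, B))
    oa = Fraction(len(O & A), len(O))
    ib = Fraction(len(I & B), len(I))
    ob = Fraction(len(O & B), len(O))
    ia = Fraction(len(I & A), len(I))
    return oa * ib * (1 - ob) * (1 - ia), oa * ib * ob * ia


class TestScoreBipartition:
    def setup_method(self):
        self.split = InOutSplit(frozenset({"o"}), frozenset({"x", "y"}))

    def test_perfect_outgroup_split(self):
        rs = score_bipartition(self.split, {"o"}, {"x", "y"})
        assert rs.s_io == 1.0
        assert rs.s_ad == 0.0

    def test_perfect_ancient_duplication(self):
        rs = score_bipartition(self.split, {"o", "x", "y"}, {"o", "x", "y"})
        assert rs.s_ad == 1.0
        assert rs.s_io == 0.0

    def test_hand_computed_mixed_case(self):
        # S_IO = (1/1)(2/2)(1-0)(1-1/2) = 0.5; S_AD has a zero factor
        rs = score_bipartition(self.split, {"o", "x"}, {"x", "y"})
        assert rs.s_io == pytest.approx(0.5)
        assert rs.s_ad == 0.0

    def test_orientation_symmetric(self):
        a, b = {"o", "x"}, {"x", "y"}
        assert score_bipartition(self.split, a, b) == \
            score_bipartition(self.split, b, a)

    def test_empty_side_rejected(self):
        with pytest.raises(ValueError):
            score_bipartition(self.split, set(), {"x"})

    def test_range_and_exact_values_random(self):
        rng = np.random.default_rng(7)
        universe = ["o", "p", "x", "y", "z"]
        split = InOutSplit(frozenset({"o", "p"}), frozenset({"x", "y", "z"}))
        for _ in range(200):
            A = {s for s in universe if rng.random() < 0.5}
            B = {s for s in universe if rng.random() < 0.5} | (set(universe) - A)
            if not A or not B:
                continue
            rs = score_bipartition(split, A, B)
            io1, ad1 = direct_products(split.outgroup, split.ingroup, A, B)
            io2, ad2 = direct_products(split.outgroup, split.ingroup, B, A)
            assert rs.s_io == pytest.approx(float(max(io1, io2)))
            assert rs.s_ad == pytest.approx(float(max(ad1, ad2)))
            assert 0.0 <= rs.s_io <= 1.0 and 0.0 <= rs.s_ad <= 1.0


def exhaustive_best_edge(tree, species_tree):
    """Score every edge from scratch; return the best max(s_io, s_ad)."""
    split = induced_split(species_tree, tree.species())
    best = -1.0
    for node, A, B, _, _ in candidate_edges(tree):
        rs = score_bipartition(split, A, B)
        best = max(best, rs.s_io, rs.s_ad)
    return best


class TestRootGeneTree:
    def test_single_outgroup_gene(self, simple_species_tree):
        tree = read_gene_tree("((o_g1,x_g1),(x_g2,y_g1));")
        rooted, score = root_gene_tree(tree, simple_species_tree)
        assert score.s_io == 1.0
        sides = {frozenset(c.leaf_labels()) for c in rooted.root.children}
        assert frozenset({"o_g1"}) in sides

    def test_ancient_duplication_root(self, simple_species_tree):
        tree = read_gene_tree("((o_g1,(x_g1,y_g1)),(o_g2,(x_g2,y_g2)));")
        rooted, score = root_gene_tree(tree, simple_species_tree)
        assert score.s_ad == 1.0
        sides = [frozenset(l.species for l in c.leaves())
                 for c in rooted.root.children]
        assert sides[0] == sides[1] == frozenset({"o", "x", "y"})

    def test_two_leaf_tree(self, simple_species_tree):
        tree = read_gene_tree("(x_g1,y_g1);")
        rooted, _ = root_gene_tree(tree, simple_species_tree)
        assert sorted(rooted.root.leaf_labels()) == ["x_g1", "y_g1"]
        assert len(rooted.root.children) == 2

    def test_single_species_tree_rooted_trivially(self, simple_species_tree):
        tree = read_gene_tree("((x_g1,x_g2),x_g3);")
        rooted, score = root_gene_tree(tree, simple_species_tree)
        assert rooted.rooted
        assert sorted(rooted.root.leaf_labels()) == ["x_g1", "x_g2", "x_g3"]

    def test_leafset_conserved_and_score_is_max(self, six_species_tree):
        rng = np.random.default_rng(11)
        pool = sorted(six_species_tree.leaf_set())
        for _ in range(50):
            n = int(rng.integers(4, 14))
            labels = [f"{pool[int(rng.integers(len(pool)))]}_g{i}"
                      for i in range(n)]
            root = random_rooted_topology(rng, labels)
            assign_node_ids(root)
            tree = GeneTree(root=root, rooted=False,
                            labels={l: None for l in labels})
            if len(tree.species()) < 2:
                continue
            rooted, score = root_gene_tree(tree, six_species_tree)
            assert sorted(rooted.root.leaf_labels()) == sorted(labels)
            best = exhaustive_best_edge(tree, six_species_tree)
            assert max(score.s_io, score.s_ad) == pytest.approx(best)

    def test_species_topology_roots_at_species_root(self):
        sp = read_species_tree("(((A,(B,C)),((D,E),F)),((G,H),(I,J)));")
        # one gene per species, gene tree congruent with the species tree
        nwk = "(((A_1,(B_1,C_1)),((D_1,E_1),F_1)),((G_1,H_1),(I_1,J_1)));"
        tree = read_gene_tree(nwk)
        rooted, score = root_gene_tree(tree, sp)
        assert score.s_io == 1.0
        sides = {frozenset(l.species for l in c.leaves())
                 for c in rooted.root.children}
        assert sides == {frozenset("ABCDEF"), frozenset("GHIJ")}

    def test_relabeling_genes_within_species_invariant(self, six_species_tree):
        t1 = read_gene_tree("((o1_g1,a_g1),(a_g2,(b_g1,c_g1)));")
        t2 = read_gene_tree("((o1_zz,a_p9),(a_q3,(b_k2,c_m4)));")
        _, s1 = root_gene_tree(t1, six_species_tree)
        _, s2 = root_gene_tree(t2, six_species_tree)
        assert (s1.s_io, s1.s_ad) == (s2.s_io, s2.s_ad)
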