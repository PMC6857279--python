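"""Ortholog and gene-duplication extraction from resolved rooted gene trees.

Genes that diverged at a speciation node are orthologs; genes that diverged
at a duplication node are paralogs.  Every cross-species gene pair in a tree
has exactly one divergence node (its most recent common ancestor), so the
pairs partition cleanly into orthologs and paralogs.

Each duplication node is mapped onto the species tree at the most recent
common ancestor of the species below it.  Its *retention* is the fraction of
the sampled species descending from that species-tree branch in which both
duplicate copies survive: |S1 ∩ S2| / |D|, with S1, S2 the species sets of
the node's two children and D the species-tree descendants of the mapped
branch restricted to the species in the analysis.  A duplication retained in
all descendant species (S1 = S2 = D) is the strongest, fully corroborated
kind of event.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Optional

import pandas as pd

from .resolver import ResolvedTree, annotate_overlap
from .tree_io import GeneTree, SpeciesTree

__all__ = [
    "OrthologRelation",
    "DuplicationEvent",
    "extract_orthologs",
    "extract_duplications",
    "orthologs_table",
    "duplications_table",
]


@dataclass(frozen=True)
class OrthologRelation:
    """Genes of two species that diverged at one speciation node."""

    species_pair: tuple[str, str]
    genes_left: frozenset[str]
    genes_right: frozenset[str]
    multiplicity: str  # one-to-one | one-to-many | many-to-one | many-to-many
    node_id: Optional[str]
    orthogroup: Optional[str] = None

    def transposed(self) -> "OrthologRelation":
        return OrthologRelation(
            species_pair=(self.species_pair[1], self.species_pair[0]),
            genes_left=self.genes_right,
            genes_right=self.genes_left,
            multiplicity={"one-to-many": "many-to-one",
                          "many-to-one": "one-to-many"}.get(
                self.multiplicity, self.multiplicity),
            node_id=self.node_id,
            orthogroup=self.orthogroup,
        )


@dataclass(frozen=True)
class DuplicationEvent:
    """A duplication node mapped onto a species-tree branch."""

    orthogroup: Optional[str]
    node_id: Optional[str]
    branch_id: str
    post_dup_sets: tuple[frozenset[str], frozenset[str]]
    retention: float
    retained_in_all: bool


def _multiplicity(n_left: int, n_right: int) -> str:
    if n_left == 1 and n_right == 1:
        return "one-to-one"
    if n_left == 1:
        return "one-to-many"
    if n_right == 1:
        return "many-to-one"
    return "many-to-many"


def _genes_by_species(node) -> dict[str, frozenset[str]]:
    out: dict[str, set[str]] = {}
    for leaf in node.leaves():
        out.setdefault(leaf.species, set()).add(leaf.label)
    return {sp: frozenset(g) for sp, g in out.items()}


def extract_orthologs(resolved: ResolvedTree | GeneTree) -> list[OrthologRelation]:
    """Read ortholog relations off every speciation node.

    At a speciation node, for every pair of children and every cross-species
    pair (p below one child, q below the other), the p-genes and q-genes
    below those children form one relation anchored at the node.  A tree
    containing a single species yields no relations.
    """
    tree = resolved.tree if isinstance(resolved, ResolvedTree) else resolved
    if not tree.rooted:
        raise ValueError("ortholog extraction requires a rooted tree")
    ann = annotate_overlap(tree)
    relations: list[OrthologRelation] = []
    for node in tree.root.postorder():
        if ann[id(node)].event != "speciation":
            continue
        per_child = [_genes_by_species(c) for c in node.children]
        for gi, gj in combinations(per_child, 2):
            for p in sorted(gi):
                for q in sorted(gj):
                    if p == q:
                        continue  # cannot occur at a speciation node
                    relations.append(OrthologRelation(
                        species_pair=(p, q),
                        genes_left=gi[p],
                        genes_right=gj[q],
                        multiplicity=_multiplicity(len(gi[p]), len(gj[q])),
                        node_id=node.node_id,
                        orthogroup=tree.name,
                    ))
    return relations


def extract_duplications(
    resolved: ResolvedTree | GeneTree,
    species_tree: SpeciesTree,
    analysis_species: Optional[set[str]] = None,
) -> list[DuplicationEvent]:
    """One event per duplication node, mapped to its species-tree branch.

    For a multifurcating duplication node, one event is emitted per pair of
    children with overlapping species sets.  ``analysis_species`` defaults
    to the species-tree leaf set and restricts the retention denominator to
    the species actually sampled.
    """
    tree = resolved.tree if isinstance(resolved, ResolvedTree) else resolved
    ann = annotate_overlap(tree)
    if analysis_species is None:
        analysis_species = set(species_tree.leaf_set())
    events: list[DuplicationEvent] = []
    for node in tree.root.postorder():
        if ann[id(node)].event != "duplication":
            continue
        kids = node.children
        for ci, cj in combinations(kids, 2):
            s1 = ann[id(ci)].species_below
            s2 = ann[id(cj)].species_below
            if not s1 & s2:
                continue
            branch = species_tree.mrca(set(s1 | s2))
            descendants = (species_tree.descendant_species(branch.node_id)
                           & frozenset(analysis_species))
            retention = len(s1 & s2) / len(descendants)
            retained_in_all = (s1 == s2 == descendants)
            events.append(DuplicationEvent(
                orthogroup=tree.name,
                node_id=node.node_id,
                branch_id=branch.node_id,
                post_dup_sets=(
                    frozenset(l.label for l in ci.leaves()),
                    frozenset(l.label for l in cj.leaves()),
                ),
                retention=retention,
                retained_in_all=retained_in_all,
            ))
    return events


def orthologs_table(
    relations: Iterable[OrthologRelation],
) -> dict[tuple[str, str], pd.DataFrame]:
    """One DataFrame per ordered species pair: (orthogroup, genes_left,
    genes_right, multiplicity); gene lists comma-joined within a cell."""
    by_pair: dict[tuple[str, str], list[OrthologRelation]] = {}
    for rel in relations:
        by_pair.setdefault(rel.species_pair, []).append(rel)
        by_pair.setdefault(rel.species_pair[::-1], []).append(rel.transposed())
    tables = {}
    for pair in sorted(by_pair):
        rows = [
            {
                "orthogroup": r.orthogroup or "",
                "genes_" + pair[0]: ",".join(sorted(r.genes_left)),
                "genes_" + pair[1]: ",".join(sorted(r.genes_right)),
                "multiplicity": r.multiplicity,
            }
            for r in sorted(by_pair[pair],
                            key=lambda r: (r.orthogroup or "",
                                           sorted(r.genes_left)))
        ]
        tables[pair] = pd.DataFrame(
            rows, columns=["orthogroup", "genes_" + pair[0],
                           "genes_" + pair[1], "multiplicity"])
    return tables


def duplications_table(events: Iterable[DuplicationEvent]) -> pd.DataFrame:
    """Global duplication table, one row per event."""
    rows = [
        {
            "orthogroup": e.orthogroup or "",
            "species_tree_branch": e.branch_id,
            "gene_tree_node": e.node_id,
            "retention": e.retention,
            "retained_in_all": e.retained_in_all,
            "genes_1": ",".join(sorted(e.post_dup_sets[0])),
            "genes_2": ",".join(sorted(e.post_dup_sets[1])),
        }
        for e in sorted(events, key=lambda e: (e.orthogroup or "",
                                               e.node_id or ""))
    ]
    return pd.DataFrame(
        rows, columns=["orthogroup", "species_tree_branch", "gene_tree_node",
                       "retention", "retained_in_all", "genes_1", "genes_2"])
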