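"""Comparative-genomics statistics computed from a completed run.

The panels mirror what comparative genomicists ask of an orthology run:
how completely each proteome is covered by orthogroups, how many
orthogroups are private to one species, how many genes have orthologs in
any/all other species, pairwise orthogroup co-membership and ortholog
counts, ortholog multiplicity profiles, and the number of duplication
events per species-tree branch (all events, and the subset retained in all
descendant species).

Orthogroup membership is read from the input tree leaf sets — one tree is
one orthogroup.  Genes absent from every tree are only visible when
per-species genome sizes are supplied, otherwise coverage is reported
relative to the genes present in the trees.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import pandas as pd

from .orthology import DuplicationEvent, OrthologRelation
from .tree_io import GeneTree, SpeciesTree

__all__ = ["StatsBundle", "compute_stats", "write_stats"]


@dataclass
class StatsBundle:
    """The statistics panel of a run; every field is a DataFrame."""

    per_species: pd.DataFrame        # coverage, species-specific OGs, any/all
    og_comembership: pd.DataFrame    # species x species, symmetric
    genes_with_ortholog: pd.DataFrame  # species x species, asymmetric
    multiplicities: pd.DataFrame     # per ordered pair histogram
    dups_per_branch: pd.DataFrame    # all + retained-in-all per branch


def compute_stats(
    trees: Iterable[GeneTree],
    relations: Iterable[OrthologRelation],
    events: Iterable[DuplicationEvent],
    species_tree: SpeciesTree,
    genome_sizes: Optional[Mapping[str, int]] = None,
) -> StatsBundle:
    trees = list(trees)
    relations = list(relations)
    events = list(events)
    species = sorted(species_tree.leaf_set())

    genes_in_ogs: dict[str, set[str]] = {sp: set() for sp in species}
    specific_ogs: dict[str, int] = {sp: 0 for sp in species}
    og_species: list[set[str]] = []
    for tree in trees:
        sps = tree.species()
        og_species.append(sps)
        for sp in sps:
            genes_in_ogs[sp] |= tree.genes_of(sp)
        if len(sps) == 1:
            specific_ogs[next(iter(sps))] += 1

    # genes of p with >=1 ortholog in q
    with_orth: dict[str, dict[str, set[str]]] = {
        p: {q: set() for q in species if q != p} for p in species}
    for rel in relations:
        p, q = rel.species_pair
        with_orth[p][q] |= rel.genes_left
        with_orth[q][p] |= rel.genes_right

    rows = []
    for sp in species:
        total = genome_sizes[sp] if genome_sizes else len(genes_in_ogs[sp])
        others = [q for q in species if q != sp]
        any_set = set().union(*(with_orth[sp][q] for q in others)) if others else set()
        all_set = (set.intersection(*(with_orth[sp][q] for q in others))
                   if others else set())
        rows.append({
            "species": sp,
            "n_genes": total,
            "n_genes_in_orthogroups": len(genes_in_ogs[sp]),
            "pct_genes_in_orthogroups": (
                100.0 * len(genes_in_ogs[sp]) / total if total else 0.0),
            "n_species_specific_orthogroups": specific_ogs[sp],
            "n_genes_with_ortholog_in_any_species": len(any_set),
            "n_genes_with_ortholog_in_all_species": len(all_set),
        })
    per_species = pd.DataFrame(rows)

    comember = pd.DataFrame(0, index=species, columns=species)
    for sps in og_species:
        for p in sps:
            for q in sps:
                comember.loc[p, q] += 1
    gw = pd.DataFrame(0, index=species, columns=species)
    for p in species:
        for q in species:
            if p != q:
                gw.loc[p, q] = len(with_orth[p][q])

    mult_classes = ["one-to-one", "one-to-many", "many-to-one", "many-to-many"]
    mcounts: dict[tuple[str, str], dict[str, int]] = {}
    for rel in relations:
        for r in (rel, rel.transposed()):
            d = mcounts.setdefault(r.species_pair, dict.fromkeys(mult_classes, 0))
            d[r.multiplicity] += 1
    mrows = [
        {"species_1": p, "species_2": q, **mcounts[(p, q)]}
        for (p, q) in sorted(mcounts)
    ]
    multiplicities = pd.DataFrame(
        mrows, columns=["species_1", "species_2", *mult_classes])

    branch_ids = [n.node_id for n in species_tree.root.preorder()]
    dup_all = dict.fromkeys(branch_ids, 0)
    dup_retained = dict.fromkeys(branch_ids, 0)
    for ev in events:
        dup_all[ev.branch_id] += 1
        if ev.retained_in_all:
            dup_retained[ev.branch_id] += 1
    dups_per_branch = pd.DataFrame({
        "branch": branch_ids,
        "n_duplications": [dup_all[b] for b in branch_ids],
        "n_retained_in_all": [dup_retained[b] for b in branch_ids],
    })

    return StatsBundle(
        per_species=per_species,
        og_comembership=comember.reset_index(names="species"),
        genes_with_ortholog=gw.reset_index(names="species"),
        multiplicities=multiplicities,
        dups_per_branch=dups_per_branch,
    )


def write_stats(bundle: StatsBundle, outdir) -> None:
    """Write one TSV per panel plus a short plain-text summary."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    panels = {
        "statistics_per_species.tsv": bundle.per_species,
        "orthogroup_comembership.tsv": bundle.og_comembership,
        "genes_with_ortholog.tsv": bundle.genes_with_ortholog,
        "ortholog_multiplicities.tsv": bundle.multiplicities,
        "duplications_per_branch.tsv": bundle.dups_per_branch,
    }
    for fname, df in panels.items():
        df.to_csv(outdir / fname, sep="\t", index=False)
    total_dups = int(bundle.dups_per_branch["n_duplications"].sum())
    retained = int(bundle.dups_per_branch["n_retained_in_all"].sum())
    lines = [
        f"species analysed\t{len(bundle.per_species)}",
        f"gene duplication events\t{total_dups}",
        f"duplications retained in all descendant species\t{retained}",
    ]
    (outdir / "summary.txt").write_text("\n".join(lines) + "\n")
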