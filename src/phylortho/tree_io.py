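"""Newick tree and species-map I/O.

Every other module operates on the lightweight :class:`TreeNode` structure
defined here.  Parsing and serialisation of Newick go through dendropy so the
package accepts the same dialect the rest of the field's tooling emits; the
internal structure exists because rooting and subtree rearrangement (the
algorithmic core of the package) need cheap prune/regraft and parent pointers.

Leaf labels carry the gene's species of origin.  By default the species is the
prefix of the label up to the first underscore (``homSap_gene17`` -> species
``homSap``); a two-column TSV species map (gene label, species id) overrides
the convention for arbitrary identifiers.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Optional

import dendropy

__all__ = [
    "TreeNode",
    "GeneLabel",
    "GeneTree",
    "SpeciesTree",
    "TreeIOError",
    "NewickParseError",
    "SpeciesResolutionError",
    "read_gene_tree",
    "read_rooted_gene_tree",
    "read_species_tree",
    "read_species_map",
    "write_tree",
    "write_tsv",
    "check_species",
]


class TreeIOError(ValueError):
    """Base class for tree-loading problems."""


class NewickParseError(TreeIOError):
    """The input text is not valid Newick."""


class SpeciesResolutionError(TreeIOError):
    """A gene-tree leaf could not be assigned to a species."""


# ---------------------------------------------------------------------------
# tree structure
# ---------------------------------------------------------------------------

class TreeNode:
    """A rooted tree node with parent pointer.

    ``label`` is the leaf label (gene label or species id) for leaves and an
    optional internal-node name otherwise.  ``species`` is set on gene-tree
    leaves after species resolution.  Branch lengths are preserved but never
    used by inference, which is purely topological.
    """

    __slots__ = ("children", "parent", "label", "length", "species", "node_id")

    def __init__(self, label: Optional[str] = None, length: Optional[float] = None):
        self.children: list[TreeNode] = []
        self.parent: Optional[TreeNode] = None
        self.label = label
        self.length = length
        self.species: Optional[str] = None
        self.node_id: Optional[str] = None

    # -- structure ----------------------------------------------------------
    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    def remove_child(self, child: "TreeNode") -> None:
        self.children.remove(child)
        child.parent = None

    def detach(self) -> "TreeNode":
        if self.parent is not None:
            self.parent.remove_child(self)
        return self

    # -- traversal ----------------------------------------------------------
    def postorder(self) -> Iterator["TreeNode"]:
        stack: list[tuple[TreeNode, bool]] = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded or node.is_leaf:
                yield node
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))

    def preorder(self) -> Iterator["TreeNode"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list["TreeNode"]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    # -- editing ------------------------------------------------------------
    def suppress_unifurcations(self) -> "TreeNode":
        """Remove degree-2 internal nodes below (and including) this node.

        Returns the (possibly new) subtree root.  Branch lengths of merged
        edges are summed when both are present.
        """
        root = self
        while len(root.children) == 1:
            child = root.children[0]
            if root.length is not None and child.length is not None:
                child.length += root.length
            child.parent = None
            root = child
        for node in list(root.postorder()):
            if node is root or node.is_leaf:
                continue
            if len(node.children) == 1:
                child = node.children[0]
                if node.length is not None and child.length is not None:
                    child.length = node.length + child.length
                parent = node.parent
                idx = parent.children.index(node)
                parent.children[idx] = child
                child.parent = parent
                node.parent = None
                node.children = []
        return root

    def copy(self) -> "TreeNode":
        clone = TreeNode(self.label, self.length)
        clone.species = self.species
        clone.node_id = self.node_id
        for child in self.children:
            clone.add_child(child.copy())
        return clone

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<TreeNode {self.label or self.node_id or 'internal'}>"


def assign_node_ids(root: TreeNode, prefix: str = "n") -> None:
    """Number internal nodes deterministically by post-order position."""
    i = 0
    for node in root.postorder():
        if node.is_leaf:
            node.node_id = node.label
        else:
            node.node_id = f"{prefix}{i}"
            i += 1


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneLabel:
    """A gene identity carrying its species of origin."""

    species_id: str
    gene_id: str
    raw_label: str


@dataclass
class GeneTree:
    """A per-orthogroup gene tree; ``rooted`` records whether the basal node
    is a meaningful root or an arbitrary display point of an unrooted tree."""

    root: TreeNode
    rooted: bool
    labels: dict[str, GeneLabel] = field(default_factory=dict)
    name: Optional[str] = None

    def species(self) -> set[str]:
        return {leaf.species for leaf in self.root.leaves()}

    def n_leaves(self) -> int:
        return sum(1 for _ in self.root.leaves())

    def genes_of(self, species_id: str) -> set[str]:
        return {l.label for l in self.root.leaves() if l.species == species_id}


@dataclass
class SpeciesTree:
    """A strictly rooted species tree; leaves are species id tokens."""

    root: TreeNode

    def __post_init__(self) -> None:
        self._index_branches()

    def _index_branches(self) -> None:
        # branch ids: leaves keep their species name, internal nodes get
        # N0 (root), N1, ... in pre-order — the naming convention readers of
        # duplication tables in this field expect.
        i = 0
        for node in self.root.preorder():
            if node.is_leaf:
                node.node_id = node.label
            else:
                node.node_id = f"N{i}"
                i += 1
        self._nodes = {n.node_id: n for n in self.root.preorder()}
        self._leaf_sets = {
            n.node_id: frozenset(l.label for l in n.leaves())
            for n in self.root.preorder()
        }

    def leaf_set(self) -> frozenset[str]:
        return self._leaf_sets[self.root.node_id]

    def node(self, node_id: str) -> TreeNode:
        return self._nodes[node_id]

    def descendant_species(self, node_id: str) -> frozenset[str]:
        return self._leaf_sets[node_id]

    def mrca(self, species: set[str]) -> TreeNode:
        """Most recent common ancestor of a set of species (the deepest node
        whose leaf set contains them all)."""
        missing = species - self.leaf_set()
        if missing:
            raise KeyError(f"species not in species tree: {sorted(missing)}")
        node = self.root
        while True:
            inner = [c for c in node.children
                     if species <= self._leaf_sets[c.node_id]]
            if len(inner) == 1:
                node = inner[0]
            else:
                return node


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _parse_newick(newick_text: str) -> TreeNode:
    try:
        dtree = dendropy.Tree.get(
            data=newick_text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise NewickParseError(f"invalid Newick: {exc}") from exc
    if dtree.seed_node is None:  # pragma: no cover - dendropy guards this
        raise NewickParseError("empty tree")

    def convert(dnode) -> TreeNode:
        if dnode.taxon is not None:
            label = dnode.taxon.label
        else:
            label = dnode.label
        node = TreeNode(label=label, length=dnode.edge.length)
        for dchild in dnode.child_nodes():
            node.add_child(convert(dchild))
        return node

    root = convert(dtree.seed_node)
    if root.is_leaf and root.label is None:
        raise NewickParseError("tree has no leaves")
    return root


def read_species_map(source) -> dict[str, str]:
    """Read a headerless two-column TSV mapping gene label -> species id."""
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source) as fh:
            text = fh.read()
    mapping: dict[str, str] = {}
    for ln, line in enumerate(text.splitlines(), 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise TreeIOError(f"species map line {ln}: expected 2 columns")
        gene, sp = parts
        if gene in mapping and mapping[gene] != sp:
            raise TreeIOError(f"species map: conflicting entries for {gene!r}")
        mapping[gene] = sp
    return mapping


def _resolve_species(raw_label: str, species_map: Optional[Mapping[str, str]]) -> GeneLabel:
    if species_map is not None:
        if raw_label not in species_map:
            raise SpeciesResolutionError(
                f"leaf {raw_label!r} not present in species map")
        sp = species_map[raw_label]
        return GeneLabel(species_id=sp, gene_id=raw_label, raw_label=raw_label)
    if "_" not in raw_label:
        raise SpeciesResolutionError(
            f"leaf {raw_label!r} has no '_' separator and no species map was given")
    sp, gene = raw_label.split("_", 1)
    if not sp:
        raise SpeciesResolutionError(f"leaf {raw_label!r} has an empty species prefix")
    return GeneLabel(species_id=sp, gene_id=gene, raw_label=raw_label)


def read_gene_tree(
    newick_text: str,
    species_map: Optional[Mapping[str, str]] = None,
    name: Optional[str] = None,
) -> GeneTree:
    """Parse an (unrooted) orthogroup gene tree.

    The tree is flagged unrooted: tree-inference programs emit unrooted trees
    and the basal node of the Newick string is an arbitrary display point.  A
    binary basal node of a >2-leaf tree is collapsed to the conventional basal
    multifurcation; rooting is the job of :mod:`phylortho.rooting`.
    """
    root = _parse_newick(newick_text)
    labels: dict[str, GeneLabel] = {}
    seen_pairs: set[tuple[str, str]] = set()
    for leaf in root.leaves():
        if leaf.label is None:
            raise NewickParseError("unlabeled leaf in gene tree")
        gl = _resolve_species(leaf.label, species_map)
        if leaf.label in labels:
            raise TreeIOError(f"duplicate leaf label {leaf.label!r}")
        if (gl.species_id, gl.gene_id) in seen_pairs:
            raise TreeIOError(
                f"duplicate (species, gene) pair {(gl.species_id, gl.gene_id)}")
        seen_pairs.add((gl.species_id, gl.gene_id))
        labels[leaf.label] = gl
        leaf.species = gl.species_id
    # represent "unrooted" canonically: basal multifurcation when possible
    if len(root.children) == 2 and len(labels) > 2:
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
    return GeneTree(root=root, rooted=False, labels=labels, name=name)


def read_rooted_gene_tree(
    newick_text: str,
    species_map: Optional[Mapping[str, str]] = None,
    name: Optional[str] = None,
) -> GeneTree:
    """Parse a gene tree whose basal node is a meaningful root.

    Use this when trees were rooted upstream (e.g. by another rooting
    program); the basal split is kept as-is instead of being collapsed to
    the unrooted representation.
    """
    root = _parse_newick(newick_text)
    root = root.suppress_unifurcations()
    labels: dict[str, GeneLabel] = {}
    for leaf in root.leaves():
        if leaf.label is None:
            raise NewickParseError("unlabeled leaf in gene tree")
        gl = _resolve_species(leaf.label, species_map)
        if leaf.label in labels:
            raise TreeIOError(f"duplicate leaf label {leaf.label!r}")
        labels[leaf.label] = gl
        leaf.species = gl.species_id
    assign_node_ids(root)
    return GeneTree(root=root, rooted=True, labels=labels, name=name)


def read_species_tree(newick_text: str) -> SpeciesTree:
    """Parse a rooted species tree.

    The basal node must be a genuine binary root: a basal trifurcation is the
    standard encoding of an *unrooted* tree, and every downstream inference
    depends on the root being meaningful.
    """
    root = _parse_newick(newick_text)
    root = root.suppress_unifurcations()
    leaves = root.leaves()
    if len(leaves) < 2:
        raise TreeIOError("species tree needs at least 2 species")
    seen: set[str] = set()
    for leaf in leaves:
        if leaf.label is None:
            raise NewickParseError("unlabeled leaf in species tree")
        if leaf.label in seen:
            raise TreeIOError(f"duplicate species {leaf.label!r} in species tree")
        seen.add(leaf.label)
        leaf.species = leaf.label
    if len(root.children) != 2:
        raise TreeIOError(
            "species tree root is not a binary split — the tree looks unrooted; "
            "please provide a rooted species tree")
    return SpeciesTree(root=root)


def check_species(
    tree: GeneTree,
    species_tree: SpeciesTree,
    on_missing: str = "error",
    log=None,
) -> GeneTree:
    """Enforce that every gene maps to a species in the species tree.

    ``on_missing='error'`` (default) raises; ``'drop'`` prunes the offending
    leaves with a warning.  Silent inclusion is never an option because a
    phantom species corrupts every overlap set downstream.
    """
    known = species_tree.leaf_set()
    missing = [l for l in tree.root.leaves() if l.species not in known]
    if not missing:
        return tree
    if on_missing == "error":
        names = ", ".join(sorted(l.label for l in missing)[:5])
        raise SpeciesResolutionError(
            f"gene(s) from species absent from the species tree: {names}")
    if on_missing != "drop":
        raise ValueError(f"unknown on_missing policy {on_missing!r}")
    if log is not None:
        log.warning(
            "%s: dropping %d gene(s) whose species is not in the species tree",
            tree.name or "<tree>", len(missing))
    for leaf in missing:
        del tree.labels[leaf.label]
        leaf.detach()
    root = tree.root.suppress_unifurcations()
    # pruning can leave empty internal nodes
    for node in list(root.postorder()):
        if not node.is_leaf and not node.children and node is not root:
            node.detach()
    root = root.suppress_unifurcations()
    assign_node_ids(root)
    tree.root = root
    return tree


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def _to_dendropy(root: TreeNode) -> dendropy.Tree:
    taxa = dendropy.TaxonNamespace()
    dtree = dendropy.Tree(taxon_namespace=taxa)

    def convert(node: TreeNode, dnode) -> None:
        if node.is_leaf:
            dnode.taxon = taxa.new_taxon(node.label)
        else:
            dnode.label = node.label
        dnode.edge.length = node.length
        for child in node.children:
            convert(child, dnode.new_child())

    convert(root, dtree.seed_node)
    return dtree


def write_tree(tree) -> str:
    """Serialise a GeneTree/SpeciesTree/TreeNode to a Newick string."""
    root = tree if isinstance(tree, TreeNode) else tree.root
    dtree = _to_dendropy(root)
    text = dtree.as_string(
        schema="newick",
        unquoted_underscores=True,
        suppress_rooting=True,
    )
    return text.strip() + "\n"


def write_tsv(table, path) -> None:
    """Write a pandas DataFrame as a TSV with a header row."""
    table.to_csv(path, sep="\t", index=False)
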