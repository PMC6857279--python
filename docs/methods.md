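# Methods

This note records the models, algorithmic choices and numerical conventions
behind `phylortho`, and what the simulation-based tests do and do not
establish.

## Scope and inputs

The package starts from per-orthogroup gene trees and a rooted species tree.
It does not perform sequence search, orthogroup inference, gene-tree
inference or species-tree inference/rooting; those belong to upstream tools.
The species tree must be rooted (a basal trifurcation is rejected with an
instruction to root it), because the in-group/out-group interpretation of
every gene tree derives from it.  Branch lengths are parsed and preserved in
output but never consulted by inference: all algorithms here are purely
topological.

Gene→species resolution uses the `species_underscore_gene` label convention
(species = prefix up to the first underscore) unless a two-column TSV map is
supplied.  Genes from species absent from the species tree are a hard error
by default; an opt-in `drop` policy prunes them with a logged warning.
Silent inclusion is never allowed since a phantom species corrupts every
overlap set downstream.

## Gene-tree rooting

For the species present in a gene tree, the induced split (O, I) is found by
descending the species tree from the root while all present species fall in
one child; the first node splitting them defines the out-group (smaller
side) and in-group.  Which side is labelled "out-group" is a reporting
convention — the two scores are symmetric under the exchange — and ties in
size are broken lexicographically.

Every edge's bipartition is scored with the two four-factor products S_IO
and S_AD over the species sets on its sides (see README for the formulas).
The literature fixes O vs I but not which gene-tree side plays A, so each
score is taken as the maximum over the two orientations (S_AD is
orientation-symmetric by construction).  The root is the edge maximising
max(S_IO, S_AD).

Numerical conventions:

* **Ties** between equally maximal edges are broken towards the edge whose
  lighter side carries fewer genes, then by post-order edge index, making
  output deterministic.  (Edges tied at S_AD = 1 form a chain of
  pre-speciation duplications; any rooting along the chain yields the same
  event-set decomposition, so the tie-break is cosmetic.)
* **Degenerate trees**: two-leaf and single-species trees are rooted on the
  longest edge (first post-order edge when lengths are absent).
* **Pathological mixing** (every edge scores 0 for both products) falls back
  to maximising the *sum* of the four S_IO factors — a smooth surrogate of
  the product — and logs a warning.  This guarantees every tree receives a
  deterministic root for downstream analysis.
* Multifurcations contribute only the bipartitions of their incident edges;
  no resolution is attempted before rooting.

## Species-overlap annotation and DL cost

A node of a rooted tree is a duplication iff the species sets below two of
its children intersect; otherwise a speciation.  At duplication nodes, one
loss is charged per (child, species) pair where the species occurs below the
node but not below that child; speciation nodes carry no losses.  The
duplication–loss cost of a subtree is the number of duplication nodes plus
all losses so charged.  Losses are counted purely from species-set
differences — not by reconciliation against the species tree — which is what
makes the correction below run at species-overlap speed.

## Hybrid resolution

A post-order traversal visits every node of the rooted tree.  At a
duplication node, the candidate clades on each side are the child itself and
its children (total topological depth ≤ 2 below the node).  Every
prune-and-regraft of one candidate clade to sisterhood with a candidate
clade on the opposite side is costed with the DL count over the node's
subtree; the cheapest strictly-improving rearrangement is applied.  The
depth-2 sub-case classification (where the smallest clade containing the
overlapping species sits on each side) is reported in the provenance log;
the action taken is defined normatively as the cost-minimal member of the
depth-2 neighbourhood, computed directly rather than via a frozen lookup
table — behaviourally equivalent and self-verifying against the brute-force
oracle, which enumerates the same neighbourhood on whole-tree copies with an
independent cost count.

Choices where the design was genuinely open:

* **Ties**: "keep" wins over any equal-cost rearrangement (only strict
  improvements fire), which avoids unstable topologies and is required for
  idempotence.  Ties among rearrangements prefer moving fewer genes, then
  enumeration order.  Equal-cost minima do occur — e.g. a rescued cherry can
  attach on either side of an adjacent split at identical cost — and both
  choices yield identical ortholog pairs and duplication events; the
  deterministic tie-break just fixes the reported topology.
* **Fixed point rather than single pass**: a rearrangement can create a new
  internal node below the visited one; passes repeat until no move fires.
  Total cost strictly decreases with every applied move, so this terminates,
  and it makes resolution idempotent (resolving a resolved tree is a
  no-op).  In practice almost all trees converge in a single pass.
* **Multifurcating duplication nodes** are handled pairwise over the
  children whose species sets overlap, largest overlap first.
* Deep coalescence carries no explicit cost of its own; only duplications
  and losses are counted.

## Ortholog and duplication extraction

Genes diverging at a speciation node are orthologs; at a duplication node,
paralogs.  Each speciation node emits, per species pair across its children,
one grouped relation (the p-genes below one child vs the q-genes below the
other), classified one-to-one / one-to-many / many-to-many from the two set
sizes.  Every cross-species gene pair is covered by exactly one node — its
divergence node — so the pairs partition into orthologs and paralogs.

Each duplication node maps to the species-tree MRCA of the species below it
(standard LCA mapping).  Retention = |S₁ ∩ S₂| / |D| where S₁, S₂ are the
children's species sets and D the species-tree descendants of the mapped
branch restricted to the analysed species; the denominator deliberately
counts species below the *species-tree* branch, not below the gene-tree
node, so unsampled lineages dilute retention.  "Retained in all descendant
species" means S₁ = S₂ = D (equivalently retention = 1).  A configurable
threshold (default 0.5) additionally flags "well-supported" events in the
output table; the threshold is exposed because no canonical value exists.

## Comparative statistics

Computed from tree leaf sets (one tree = one orthogroup), the ortholog
relations and the duplication table: per-species orthogroup coverage
(relative to supplied genome sizes when given, else to genes observed),
species-specific orthogroup counts, genes with orthologs in any/all other
species, pairwise orthogroup co-membership (symmetric) and
genes-with-ortholog counts (asymmetric), multiplicity histograms per ordered
pair, and per-branch duplication counts (all, and retained-in-all, the
latter always a branch-wise subset).

## Simulator

The generator emulates gene-family evolution along the rooted species tree:
one gene enters the species-tree root; on each branch, each lineage
duplicates at rate λ (`dup_rate`, events per lineage per unit branch length)
and dies at rate μ (`loss_rate`); survivors split at species-tree nodes.
Exponential waiting times are drawn from a single seeded stream, so a seed
fixes the dataset byte-for-byte.  Families with fewer than two surviving
genes are redrawn (capped attempts), and rate combinations whose expected
family size exceeds `size_cap` are rejected up front.

Ground-truth duplication events are those whose both copies leave surviving
descendants, recorded as the unordered pair of post-duplication gene sets;
ground-truth orthologs are cross-species pairs whose divergence node is a
speciation.  Tree-inference error is emulated by k random NNI moves
(`nni_moves`) applied to the true topology before the tree is handed,
unrooted, to the pipeline.

Default study conditions: 12 species on a balanced unit-branch-length tree,
500 families, λ = 0.05 — chosen so families average about one duplication
event, the density typical of the fly-scale simulated datasets used to
benchmark duplication inference — μ = 0 and k = 0, with losses and noise
switched on per experiment.

What the simulator does *not* model: explicit multispecies-coalescent
(incomplete lineage sorting is emulated only insofar as NNI noise creates
gene-tree/species-tree incongruence), rate heterogeneity across branches and
families, sequence-level evolution and re-inference.  Passing benchmarks
therefore demonstrate robustness to topological error around duplication
nodes, not to every error process in real data.

## Benchmark

An inferred duplication is a true positive iff its two post-duplication gene
sets exactly equal a ground-truth event's sets (each truth event matched at
most once); precision = TP/inferred, recall = TP/truth, F = 2PR/(P+R) with
F = 0 on empty denominators.  The benchmark runs the pure species-overlap
pipeline and the hybrid resolver on identical inputs.  Under the default
noiseless conditions both methods recover every event and ortholog exactly
(F = 1.0); with two NNI moves of noise per tree, the overlap method scores
F ≈ 0.72 and the hybrid resolver F ≈ 0.84 across seeds, and the hybrid
advantage holds in 20/20 seeds at 500 families.

## Test-suite problem sizes

The resolver-vs-oracle equivalence suite runs exhaustively over all rooted
binary tree shapes with up to 6 leaves crossed with all species assignments
over up to 4 species (~28,000 trees), plus 1,000 random 12-leaf trees over 5
species; the exhaustive layer is capped at 6 leaves because the assignment
grid grows as (shapes × 4^n) and 6 leaves already exercises every depth-2
sub-case geometry.  Simulation suites use 500 families × 12 species per
seed, and 20 seeds for the noise comparison.

## Known limitations

* The depth-2 neighbourhood cannot repair errors that displace a gene more
  than two levels from its true position; such cases remain over-counted
  duplications, which is the main gap between the hybrid F-score and 1.
* The overlap-based loss count ignores the species tree, so equally
  parsimonious local topologies can disagree with species-tree congruence;
  event and ortholog output are unaffected, only the reported resolved
  topology varies within the cost-minimal set.
* Rooting quality degrades when the out-group is heavily duplicated *and*
  partially lost; the surrogate fallback guarantees a root but not a good
  one, and such trees are flagged in the log.
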