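# Methods

This note documents the models, algorithms, numerical choices, and open
design decisions behind `sdagsearch`, in the spirit of a statistical
package's model documentation.

## The subsplit DAG

Taxa are held in a fixed order; clades are bitmasks over that order and are
totally ordered by "the member of the first differing taxon sorts first".
A subsplit stores its lesser clade on the left.  Two degenerate forms are
admitted: leaf subsplits `{{x}, ∅}` and the universal ancestor
`ρ = {∅, full}`.  ρ deliberately violates the left-before-right rule
(nonempty clades sort before the empty clade) so that all edges out of ρ
partition its *right* clade; this keeps root splits on the same code path
as every other parent/child relation and avoids a special root node class.
Leaves are modeled as degenerate subsplits; any alternative encoding is
isomorphic, since leaf nodes carry no choices.

Edges are identified by the triple (parent subsplit, partitioned clade,
child subsplit) and carry one branch length (substitutions/site).  Edges
out of ρ are pinned to length 0 and excluded from likelihood products.
Structural operations (edge completion, NNIs) insert edges with a `None`
sentinel length; any likelihood computation touching a sentinel raises, so
a length must be assigned deliberately before evaluation.  Acyclicity needs
no checking: every edge strictly decreases the taxon-set union.

Topology counting is the standard product-sum dynamic program (product
over a node's nonempty clades of the sum over the clade's children);
enumeration walks the same recursion in sorted-edge order, making both the
count and the enumeration order deterministic.  An sDAG is *edge-complete*
when it contains an edge for every compatible (parent, clade, child) triple
among its nodes; `complete_edges` is idempotent.

## Likelihood model

Jukes–Cantor throughout: transition matrix `1/4 + 3/4·e^{-4t/3}` on the
diagonal, stationary frequencies 1/4 at the root, a single rate category,
and site independence.  Generalizing to GTR with fixed parameters would
change only the transition-matrix function; rate variation is out of scope.
Branch lengths are optimized, never marginalized.

IUPAC ambiguity codes, gaps, and `?` are scored as fully ambiguous
observations (partial vector of ones) — the standard Felsenstein
convention.  This is a package decision, not something the model forces;
alternatives (e.g. dropping gapped columns) can be applied upstream.

Felsenstein pruning keeps partial likelihood vectors as (sites × 4) arrays
rescaled per node and per site so the maximum entry is 1, with the scale
factors accumulated additively in log space.  Branch-length optimization is
coordinate ascent: bounded Brent per edge over [1e-6, 10]
substitutions/site (line-search tolerance 1e-5), sweeping until the largest
per-edge change falls below 1e-4 or 5 sweeps have run.  A Brent proposal
that does not improve the objective is discarded, so the objective is
monotone across sweeps even when the line search is sloppy near a boundary.
These values live in `OptimizerConfig`.

## NNIs on an sDAG

For a source edge `(t, w) → s` with `t = {X∪Y, Z}` and `s = {X, Y}`
(eligibility: `t ≠ ρ` and `s` internal — leaf children have nothing to
swap, ρ has no sibling clade), the two swaps produce `t′ = {X∪Z, Y},
s′ = {X, Z}` and `t′ = {Y∪Z, X}, s′ = {Y, Z}`.  Application adds (a) the
central edge `t′ → s′`, (b) `u → t′` for every existing `u → t`, and (c)
child edges mirroring the descendants of the affected clades.  Each new
edge therefore has a natural pre-existing *counterpart* edge; counterparts
seed branch lengths (below).  Candidate generation produces two proposals
per eligible edge, deduplicates by central edge (first-generated wins, in
source-edge order), and drops proposals that add no node and no edge key.

When the pre-NNI sDAG is edge-complete, every topology new to the post-NNI
sDAG (classes a–c only) contains the central edge and is one NNI away from
a pre-NNI topology.  The tests assert both properties by enumeration, and
only for edge-complete inputs and the bare (completion-free) application:
the *additional* compatible edges added afterwards — all of them for top
pruning, only those touching `t′`/`s′` for generalized pruning — may
legitimately create further topologies outside both guarantees.

## Top pruning

Choice maps record, per edge, a parent+sibling pair (undefined for edges
out of ρ) and a left/right child pair (undefined into leaves).  The best
known tree for an edge starts from that edge and repeatedly fills missing
children from the leafward map and missing parent+sibling pairs from the
rootward map until the edge set is a tree; branch lengths are the sDAG's
stored lengths.  When the DAG is initialized from a likelihood-ordered tree
list, every edge's choices and length come from the first listed tree
containing it.

New edges (from completion or NNIs) get choices by a **greedy slot-wise
argmax**: slots are resolved in the order (parent+sibling jointly, left
child, right child); each candidate — an incident edge of the current DAG —
is scored by the full likelihood of the resulting best known tree; ties
break by edge-key order.  Because scoring a candidate requires a complete
tree, all still-unassigned slots (of the edge under consideration and of
other new edges) are provisionally filled with their minimal-edge-key
candidates first.  Whether the reference strategy resolves slots jointly or
slot-wise is not determinable from its description; slot-wise is chosen as
the deterministic, cheaper reading, and the joint variant would only ever
improve the approximation, not change any contract.

The top-pruning score of an NNI is the log likelihood of the best known
tree through its central edge, evaluated on a scratch overlay of the
post-NNI sDAG: class a–c edges inherit their counterpart's branch length,
completion extras default to 0.1 substitutions/site, only the central
edge's slots are argmax-refined, and only the central edge's length is
optimized (config switch `optimize_all_new_edges` extends optimization to
every new edge of the best known tree).  Optimizing just the new degree of
freedom is the cheapest reading consistent with scoring "the" tree of the
central edge; adopted NNIs get their completion edges optimized at
adoption time anyway.

The search loop: pop the best-scoring proposal; enlarge with full edge
completion; assign choices and optimized lengths to all new edges; insert
freshly scored proposals for newly enabled NNIs.  Stored scores are *never*
recomputed, so pop order can rest on values computed against an earlier
DAG — the documented price of never re-evaluating.  A popped entry whose
content has meanwhile been absorbed by completions is discarded without
consuming an iteration (growth is monotone, so "non-enlarging" is
permanent).  Stopping: an iteration cap and/or a score threshold.

## Generalized pruning

The GP likelihood of edge `e` is `Σ_j log( S_j(e) / |T_e| )` with
`S_j(e) = Σ_{τ∈T_e} p_ψ(Y_j|τ)`, i.e. a composite likelihood averaging
per-site tree likelihoods under the uniform prior on `T_e`.  The dynamic
program derives from the factorization of `S_j` over independent subtree
choices:

* leafward: `p̂(t, w) = Σ_{(t,w)→c} P(ψ) p(c)` and
  `p(s) = p̂(s, left) ⊙ p̂(s, right)` (indicators at leaves, ones for empty
  clades) — unnormalized sums whose term counts are subtree counts;
* rootward: `r(ρ) = 1/4`, `above(e) = r(t) ⊙ p̂(t, sibling clade)`,
  `r(s) = Σ_{e′ into s} P(ψ)ᵀ above(e′)`;
* per site: `S_j(e) = above(e) · P(ψ(e)) p(s)`.

Running the same recursions on integer counts yields `|T_e|` and, as a
corollary, the partition identity `Σ_e |T_e| = |T_{(node, clade)}|` over
sibling edges.  All vectors carry per-site log-scale accumulators.  The
contract is equality with the enumeration oracle `gp_likelihood_bruteforce`
(asserted to 1e-9 on hundreds of randomized instances), not fidelity to any
particular published recursion.  The *true* marginal likelihood (averaging
whole-alignment likelihoods) is provided by enumeration only, for tests and
contrast; it coincides with GP at one site or `|T_e| = 1` and differs
otherwise.

GP branch-length optimization maximizes, for each new edge, that edge's own
GP likelihood (coordinate Brent, old edges untouched).  Caches are rebuilt
per evaluation rather than incrementally invalidated — correctness over
constant-factor speed; at the problem sizes this package targets the
rebuild is cheap, and it is the main cost of the GP search.  Scratch
overlays for scoring hypothetical NNIs initialize lengths from counterpart
edges (0.1 default), optimize the new lengths, and are discarded if the
proposal is not applied.  The GP search mirrors the top-pruning loop but
uses around-new-nodes completion, per its design.  An optional
initialization step refines the starting lengths against either each
edge's own GP likelihood (`"per_edge"`) or the whole-DAG composite
(`"whole"`, the GP likelihood at the ρ edges); both are exposed because the
intended variant is ambiguous, and both default to off.

## Distributions and evaluation

Edge probabilities are vectors over the outgoing edges of every
(node, clade) choice point; a topology's probability is the product over
its edges, which normalizes over the DAG's topologies by construction.
Fitting is frequency counting (choice points unvisited by the sample get
the uniform vector); a conditional clade distribution is the special case
where choice points sharing a clade carry identical vectors, and
`is_clade_conditional` tests this to 1e-12.  Credible sets take topologies
in decreasing density order (ties by canonical Newick) until the level is
reached.  Subsplit credibility counts internal subsplits only — leaves are
in every sDAG and ρ is structural, so including either would inflate both
fractions toward 1.

## Synthetic data

The generators stand in for curated benchmark alignments: uniform random
rooted topologies (sequential attachment — taxon k+1 grafts onto one of the
2k−1 edges, including the root edge, giving exact uniformity over the
(2n−3)!! topologies), iid exponential branch lengths with mean 0.1
substitutions/site (a typical phylogenetic scale), and JC sequence
simulation from a uniform root state.  What they do not emulate: rate
heterogeneity across sites and lineages, base-composition bias, indels and
alignment error, and the deep, data-driven posterior concentration of real
benchmark data sets.  Passing tests therefore demonstrate correctness of
the structures and estimators and recovery under the assumed model, not
performance on real data at scale.

Problem sizes used by the test suite and the acceptance script — 3–7 taxa,
1–1000 sites, hundreds of randomized sDAG instances, searches of ≤30
iterations — are the package's chosen study conditions: small enough that
every quantity has an exhaustive or closed-form oracle, which is the point
of the exercise.

## Numerical and degenerate-input choices

* PLV rescaling guards all-zero sites (possible only at zero branch
  lengths with conflicting states) and returns −inf rather than raising.
* Brent bounds [1e-6, 10] effectively make 1e-6 the "zero length"; tests
  asserting collapse to zero check `< 1e-4`.
* The exhaustive ML tree breaks the root-placement tie of a reversible
  model toward the enumeration order; searches do not depend on which
  rooting wins, only on reaching the generating topology's support.
* Serialization prints subsplits as `left|right` member lists and lengths
  via `repr`, so round-trips are bit-exact; sentinel lengths serialize as
  `NA`.

## Known limitations

* Performance: likelihood caching is per-call, not incremental; the
  constant-time best-known-tree update and linear-time GP updates of a
  production C++ implementation are out of scope.  Costs grow with DAG
  size, so long searches slow down per iteration.
* JC only, rooted trees only, no rate variation, no branch-length
  marginalization or distributions (a variational layer could sit on top).
* The alternative "add only the five best-known-tree edges" search variant
  is deliberately not implemented: it cannot reach all subsplits.
* `fit_edge_probabilities` requires samples already contained in the DAG;
  rootings-union construction and EM fitting for unrooted samples are out
  of scope.
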