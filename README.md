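# sdagsearch

Systematic search for high posterior density phylogenies on subsplit DAGs.

## The problem

Bayesian phylogenetics asks for a posterior distribution over rooted tree
topologies, a space of super-exponential size whose high-confidence region
is nevertheless tiny.  MCMC explores this space as a random walk and wastes
most proposals; maximum-likelihood search is systematic but returns a single
tree.  `sdagsearch` implements a middle road: represent *many* topologies at
once in a **subsplit directed acyclic graph (sDAG)** and enlarge that
structure systematically until it contains a credible set of topologies.
It is aimed at researchers in Bayesian phylogenetic inference — in
particular anyone experimenting with variational or optimization-based
posterior approximations that take an sDAG as their support.

## The structure and the two search criteria

A **subsplit** `s = {X, Y}` is an ordered pair of disjoint taxon sets
labeling an internal node: the bipartition of the taxa below that node.  An
sDAG has subsplits as nodes and edges `(t, X̲) → s` connecting a parent `t`
to a child `s` that partitions one designated clade `X` of `t`.  Any
tree-shaped subgraph containing all leaves is a rooted topology, so the sDAG
spanned by a set of topologies typically contains extra topologies beyond
its inputs — the leverage the search exploits.  Each edge carries one branch
length `ψ(e)`, so topologies in the sDAG correspond one-to-one to trees.

An **NNI on an sDAG** enlarges rather than modifies: for an edge with
`t = {X∪Y, Z}`, `s = {X, Y}`, swapping `Y` and `Z` adds subsplits
`t′ = {X∪Z, Y}` and `s′ = {X, Z}` plus a small set of connecting edges,
among them the *central edge* `t′ → s′`.  Two criteria rank candidate NNIs
under the Jukes–Cantor model with fixed branch lengths:

* **Top pruning** scores an NNI by the classical Felsenstein likelihood of
  the *best known tree* through its central edge — a single tree assembled
  by recursively applying per-edge *choice maps* (each edge remembers a
  parent+sibling pair and a left/right child pair, seeded from the
  highest-likelihood input tree containing the edge, extended by argmax for
  new edges).

* **Generalized pruning (GP)** scores an NNI by a per-edge topology-marginal
  composite likelihood: with `T_e` the trees of the post-NNI sDAG containing
  the central edge `e`,

  `L_GP(e) = ∏_j  Σ_{τ ∈ T_e}  p_ψ(Y_j | τ) · p(τ|e)` ,

  with sites `j` averaged independently (hence *composite*) and a uniform
  prior `p(τ|e) = 1/|T_e|`.  A two-pass dynamic program over the sDAG shares
  partial likelihood vectors across all topologies, so the cost is linear in
  the number of edges; a brute-force enumeration oracle validates it.

Both searches pop the highest-scoring NNI from a queue, enlarge the sDAG,
optimize the new branch lengths by coordinate-wise Brent, and insert freshly
scored candidates (stored scores are never recomputed).  The package also
provides probability distributions on sDAG edges (topology probabilities,
frequency-count fitting, sampling, the conditional-clade special case) and
posterior-coverage metrics (credible sets, density coverage, subsplit
credibility) for evaluating the resulting sDAGs.

## Worked example

```python
from sdagsearch import (EdgeProbabilities, Which, count_topologies,
                        make_clade, make_subsplit, parse_newick_topology,
                        sdag_from_topologies, topology_probability)
from sdagsearch.simulate import default_taxa

taxa = default_taxa(7)
t1 = parse_newick_topology("(0,(1,(2,(3,(4,(5,6))))));", taxa)
t2 = parse_newick_topology("((0,1),(2,(3,((4,6),5))));", taxa)
dag = sdag_from_topologies([t1, t2])
print(count_topologies(dag))
```

prints `4`: the union of the two topologies also contains the two mixtures
of their root splits and `{4,5,6}` resolutions.  Assigning probability 0.4
to the root split `{{0,1},{2,3,4,5,6}}` and 0.3 to the resolution
`{{4},{5,6}}` (uniform elsewhere, see `examples/build_and_count_sdag.py`)
gives

```
P(((0,1),(2,(3,(4,(5,6)))))) = 0.12   # 0.4 x 0.3
sum over all 4 topologies = 1.0
```

— the probability of a topology is the product of its edges' conditional
probabilities, and the edge distributions normalize over the sDAG.  Running
`examples/top_pruning_search.py` (5 taxa, 500 simulated sites) prints the
search trace, e.g.

```
iter  tp-log-lik   nodes  edges  topologies
   1    -2280.50      12     14           2
   2    -2280.50      14     19           3
   ...
final sDAG contains the generating topology: True
```

where each row is one applied NNI: its best-known-tree log likelihood and
the resulting sDAG size.  The other scripts in `examples/` demonstrate the
GP likelihood against its enumeration oracle and the posterior-coverage
metrics.

A thin CLI wraps the same functionality:
`sdagsearch simulate|build-sdag|tp-search|gp-search|evaluate --help`.

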