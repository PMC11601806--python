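"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's PLV/dynamic-programming code paths:
likelihoods are computed by exhaustive summation over internal-node state
assignments, and NNI neighborhoods by applying every proposal to a
single-topology DAG and reading off the one new topology.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from sdagsearch import (
    RootedTopology,
    Tree,
    apply_nni,
    enumerate_topologies,
    jc_transition_matrix,
    proposals_for_edge,
    sdag_from_topologies,
)
from sdagsearch.nni import edge_is_nni_eligible
from sdagsearch.phylo import Alignment


def brute_force_tree_log_likelihood(tree: Tree, aln: Alignment) -> float:
    """Sum over all internal-node state assignments, site by site."""
    topo = tree.topology
    lengths = {
        k.child.union.mask: v
        for k, v in tree.lengths.items()
        if not k.parent.is_rho
    }

    internal: list = []

    def collect(node):
        if node.children is None:
            return
        internal.append(node)
        for child in node.children:
            collect(child)

    collect(topo.root)

    total = 0.0
    for site in range(aln.n_sites):
        site_prob = 0.0
        leaf_partials = {
            i: aln.leaf_partials(i)[site] for i in range(aln.taxa.n)
        }
        for assignment in itertools.product(range(4), repeat=len(internal)):
            states = {id(n): s for n, s in zip(internal, assignment)}
            prob = 0.25  # root state prior
            ok = True
            for node in internal:
                parent_state = states[id(node)]
                for child in node.children:
                    matrix = jc_transition_matrix(lengths[child.mask])
                    if child.children is None:
                        prob *= float(
                            matrix[parent_state] @ leaf_partials[child.taxon]
                        )
                    else:
                        prob *= matrix[parent_state, states[id(child)]]
                if prob == 0.0:
                    ok = False
                    break
            if ok:
                site_prob += prob
        total += math.log(site_prob)
    return total


def nni_neighbors(topo: RootedTopology) -> set[RootedTopology]:
    """All topologies one NNI away from `topo` (tree-level NNI)."""
    d = sdag_from_topologies([topo])
    out: set[RootedTopology] = set()
    for key in d.edges():
        if not edge_is_nni_eligible(key):
            continue
        for p in proposals_for_edge(key):
            enlarged = apply_nni(d, p, completion="none")
            for t in enumerate_topologies(enlarged):
                if t != topo:
                    out.add(t)
    return out
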