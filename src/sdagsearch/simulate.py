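"""Synthetic data: random rooted trees and Jukes-Cantor sequence simulation.

These generators stand in for the curated benchmark alignments a production
analysis would use: topologies are drawn uniformly from the space of rooted
bifurcating labeled topologies, branch lengths are exponential with mean
0.1 substitutions/site (a typical phylogenetic scale), and sequences evolve
site-independently under JC69 from a uniform root state.  All randomness
flows through a single numpy Generator, so identical configurations give
byte-identical FASTA/Newick output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from ._config import OptimizerConfig
from .phylo import (
    Alignment,
    NUCLEOTIDES,
    PhyloError,
    jc_transition_matrix,
    optimize_branch_lengths,
    tree_log_likelihood,
)
from .subsplits import SubsplitError, TaxonSet
from .treeio import EdgeKey, RootedTopology, Tree, _internal, _leaf, _Node

RngLike = Union[int, np.random.Generator]


def as_rng(seed: RngLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class SimConfig:
    """Study conditions for a simulated data set."""

    n_taxa: int
    n_sites: int
    seed: int
    branch_length_mean: float = 0.1

    def __post_init__(self) -> None:
        if self.n_taxa < 2:
            raise SubsplitError("at least 2 taxa are required")
        if self.n_sites < 1:
            raise PhyloError("at least 1 site is required")


def default_taxa(n: int) -> TaxonSet:
    """Taxon labels "0" .. "n-1", matching the worked examples' convention."""
    return TaxonSet(tuple(str(i) for i in range(n)))


def _as_taxa(taxa: Union[int, TaxonSet]) -> TaxonSet:
    return default_taxa(taxa) if isinstance(taxa, int) else taxa


# ---------------------------------------------------------------------------
# Random and exhaustive topology generation
# ---------------------------------------------------------------------------

def random_rooted_topology(
    taxa: Union[int, TaxonSet], rng: RngLike
) -> RootedTopology:
    """Uniform draw from rooted bifurcating labeled topologies.

    Sequential random attachment: taxon k+1 is grafted onto one of the
    2k-1 edges (counting the root edge) of the topology on the first k
    taxa, each with equal probability.  Every topology on k+1 taxa arises
    from exactly one (topology, edge) pair, so the draw is uniform over
    the (2n-3)!! topologies.
    """
    ts = _as_taxa(taxa)
    if ts.n < 2:
        raise SubsplitError("at least 2 taxa are required")
    rng = as_rng(rng)

    tree = 0  # nested [left, right] lists; ints are leaves

    def nodes(sub) -> int:
        if isinstance(sub, int):
            return 1
        return 1 + nodes(sub[0]) + nodes(sub[1])

    def attach(sub, k: int, leaf: int):
        """Graft `leaf` above the k-th node (preorder) of `sub`."""
        if k == 0:
            return [sub, leaf]
        k -= 1
        if isinstance(sub, int):
            raise AssertionError("attachment index out of range")
        left_size = nodes(sub[0])
        if k < left_size:
            sub[0] = attach(sub[0], k, leaf)
        else:
            sub[1] = attach(sub[1], k - left_size, leaf)
        return sub

    for leaf in range(1, ts.n):
        k = int(rng.integers(nodes(tree)))
        tree = attach(tree, k, leaf)

    def build(sub) -> _Node:
        if isinstance(sub, int):
            return _leaf(sub)
        return _internal(build(sub[0]), build(sub[1]))

    return RootedTopology(ts, build(tree))


def all_rooted_topologies(taxa: Union[int, TaxonSet]) -> list[RootedTopology]:
    """Every rooted bifurcating labeled topology on the taxon set.

    There are (2n-3)!! of them; intended for n <= 7 (10395 topologies).
    """
    ts = _as_taxa(taxa)
    if ts.n > 8:
        raise SubsplitError("exhaustive enumeration is capped at 8 taxa")

    def grow(partials: list, leaf: int) -> list:
        out = []
        for sub in partials:

            def attachments(s):
                yield [s, leaf]
                if not isinstance(s, int):
                    for left in attachments(s[0]):
                        yield [left, s[1]]
                    for right in attachments(s[1]):
                        yield [s[0], right]

            out.extend(attachments(sub))
        return out

    partials: list = [0]
    for leaf in range(1, ts.n):
        partials = grow(partials, leaf)

    def build(sub) -> _Node:
        if isinstance(sub, int):
            return _leaf(sub)
        return _internal(build(sub[0]), build(sub[1]))

    return sorted(RootedTopology(ts, build(s)) for s in partials)


def random_tree(
    taxa: Union[int, TaxonSet],
    rng: RngLike,
    branch_length_mean: float = 0.1,
) -> Tree:
    """Random topology with iid exponential branch lengths."""
    rng = as_rng(rng)
    topo = random_rooted_topology(taxa, rng)
    lengths = {
        k: (0.0 if k.parent.is_rho else float(rng.exponential(branch_length_mean)))
        for k in sorted(topo.edge_keys())
    }
    return Tree(topo, lengths)


# ---------------------------------------------------------------------------
# Sequence simulation
# ---------------------------------------------------------------------------

def simulate_jc_alignment(
    tree: Tree, n_sites: int, rng: RngLike
) -> Alignment:
    """Evolve iid sites down the tree under JC69 from a uniform root state."""
    rng = as_rng(rng)
    topo = tree.topology
    by_mask = {}
    for k in topo.edge_keys():
        if k.parent.is_rho:
            continue
        if tree.lengths[k] is None:
            raise PhyloError(f"unset branch length on {k!r}")
        by_mask[k.child.union.mask] = tree.lengths[k]

    states = np.zeros((topo.taxa.n, n_sites), dtype=np.int64)

    def evolve(node: _Node, parent_states: np.ndarray) -> None:
        if node.children is None:
            states[node.taxon] = parent_states
            return
        for child in node.children:
            matrix = jc_transition_matrix(by_mask[child.mask])
            u = rng.random(n_sites)
            # inverse-CDF draw per site from the parent state's row
            cdf = matrix.cumsum(axis=1)[parent_states]
            child_states = (u[:, None] > cdf).sum(axis=1)
            evolve(child, child_states)

    root_states = rng.integers(0, 4, n_sites)
    evolve(topo.root, root_states)

    sequences = {
        lab: "".join(NUCLEOTIDES[s] for s in states[i])
        for i, lab in enumerate(topo.taxa.labels)
    }
    return Alignment.from_sequences(sequences, topo.taxa)


# ---------------------------------------------------------------------------
# Exhaustive maximum-likelihood tree (small n)
# ---------------------------------------------------------------------------

def exhaustive_ml_tree(
    aln: Alignment,
    config: Optional[OptimizerConfig] = None,
    init_length: float = 0.1,
) -> Tree:
    """The maximum-likelihood tree by enumerating all rooted topologies.

    Each topology's branch lengths are optimized by coordinate Brent; ties
    (e.g. the root-placement invariance of a reversible model) break toward
    the enumeration order.  Intended for n <= 6.
    """
    if aln.taxa.n > 6:
        raise PhyloError("exhaustive ML search is capped at 6 taxa")
    best: Optional[tuple[float, Tree]] = None
    for topo in all_rooted_topologies(aln.taxa):
        edges = sorted(topo.edge_keys())
        init = {
            k: (0.0 if k.parent.is_rho else init_length) for k in edges
        }

        def objective(lengths: dict[EdgeKey, float]) -> float:
            return tree_log_likelihood(Tree(topo, lengths), aln)

        free = [k for k in edges if not k.parent.is_rho]
        opt = optimize_branch_lengths(objective, free, init, config)
        ll = objective(opt)
        if best is None or ll > best[0] + 1e-12:
            best = (ll, Tree(topo, opt))
    assert best is not None
    return best[1]
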