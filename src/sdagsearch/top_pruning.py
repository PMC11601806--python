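"""Top pruning: choice maps, best known trees, and the NNI search they drive.

Top pruning scores an NNI by the classical Felsenstein likelihood of a
single tree -- the *best known tree* through the NNI's central edge.  The
machinery is a pair of *choice maps* over the edges of the subsplit DAG:

* the rootward map gives each edge a parent edge and a sibling edge
  (undefined for edges out of the universal ancestor rho);
* the leafward map gives each edge a left and right child edge (undefined
  per side for sides ending in leaves).

Recursively applying the maps from any edge grows the edge into a full tree
on the taxon set.  When the DAG is built from a likelihood-ordered list of
trees, each edge's choices (and its branch length) come from the first --
highest-likelihood -- listed tree containing the edge, so the best known
tree is a cheap stand-in for the maximum-likelihood tree through the edge.

Edges added later (by completion or NNIs) get their choices from a greedy
argmax: each unresolved slot is filled, in the order (parent+sibling
jointly, left child, right child), by the candidate incident edge whose
resulting best known tree has the highest likelihood, ties broken by edge
key.  While a slot is under evaluation, any still-unresolved slots are
provisionally filled with their minimal-edge-key candidates so every
candidate evaluation scores a complete tree.

The search itself repeatedly pops the highest-scoring NNI from a queue,
enlarges the DAG (with full edge completion), extends the choice maps, and
inserts freshly scored proposals for the newly enabled NNIs; scores of
proposals already queued are never recomputed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from ._config import SearchConfig
from .nni import NNIProposal, apply_nni_detailed, candidate_nnis, proposal_is_enlarging
from .phylo import Alignment, brent_maximize, tree_log_likelihood
from .sdag import (
    SdagError,
    SubsplitDAG,
    complete_edges,
    count_topologies,
    sdag_from_trees,
    tree_from_sdag,
)
from .subsplits import Which
from .treeio import EdgeKey, RootedTopology, Tree, _internal, _leaf


class TopPruningError(ValueError):
    pass


@dataclass
class ChoiceEntry:
    """The chosen neighbor edges of one sDAG edge.

    ``None`` means either "not applicable" (no parent for edges out of rho,
    no child on a leaf side) or "not yet assigned"; which of the two is
    determined by the edge's structure.
    """

    parent: Optional[EdgeKey] = None
    sibling: Optional[EdgeKey] = None
    left: Optional[EdgeKey] = None
    right: Optional[EdgeKey] = None


@dataclass
class QueueEntry:
    """A scored NNI proposal; the score is never updated once stored."""

    log_likelihood: float
    proposal: NNIProposal


@dataclass
class TPIteration:
    """Per-iteration search trace record."""

    iteration: int
    central_edge: EdgeKey
    log_likelihood: float
    n_nodes: int
    n_edges: int
    n_topologies: int


@dataclass
class TPState:
    """A subsplit DAG with choice maps and a scored NNI queue."""

    sdag: SubsplitDAG
    choice: dict[EdgeKey, ChoiceEntry]
    aln: Alignment
    config: SearchConfig = field(default_factory=SearchConfig)
    queue: list[QueueEntry] = field(default_factory=list)
    edge_first_tree: dict[EdgeKey, int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Initialization from a likelihood-ordered tree list
# ---------------------------------------------------------------------------

def _tree_neighbor_choices(tree: Tree) -> dict[EdgeKey, ChoiceEntry]:
    """Each edge's parent/sibling/children within a single tree."""
    keys = tree.topology.edge_keys()
    by_child = {k.child: k for k in keys}
    by_slot = {(k.parent, k.which): k for k in keys}
    out = {}
    for k in keys:
        entry = ChoiceEntry()
        if not k.parent.is_rho:
            entry.parent = by_child[k.parent]
            entry.sibling = by_slot.get((k.parent, k.which.other))
        if not k.child.is_leaf:
            entry.left = by_slot[(k.child, Which.LEFT)]
            entry.right = by_slot[(k.child, Which.RIGHT)]
        out[k] = entry
    return out


def init_from_tree_list(
    trees: Sequence[Tree],
    aln: Alignment,
    config: Optional[SearchConfig] = None,
) -> TPState:
    """Steps 1-4 of the top-pruning algorithm.

    Builds the DAG spanned by the trees; every edge takes its branch length
    and neighbor choices from the first tree of the list containing it (the
    list must be ordered by decreasing likelihood -- checked when the
    config's `verify_tree_order` is set); then adds all compatible edges,
    assigns their choices by argmax, and optimizes their branch lengths
    against their best known trees.
    """
    cfg = config or SearchConfig()
    if not trees:
        raise TopPruningError("at least one input tree is required")
    if cfg.verify_tree_order:
        lls = [tree_log_likelihood(t, aln) for t in trees]
        if any(a < b - 1e-9 for a, b in zip(lls, lls[1:])):
            raise TopPruningError(
                "input trees are not ordered by decreasing likelihood"
            )
    dag, first = sdag_from_trees(trees)
    per_tree = [_tree_neighbor_choices(t) for t in trees]
    choice = {k: replace(per_tree[i][k]) for k, i in first.items()}
    state = TPState(dag, choice, aln, cfg, edge_first_tree=dict(first))

    before = dag.edge_keys()
    complete_edges(dag, in_place=True)
    new_edges = sorted(dag.edge_keys() - before)
    for k in new_edges:
        dag.set_branch_length(k, cfg.default_branch_length)
    extend_argmax(state, new_edges)
    return state


# ---------------------------------------------------------------------------
# Best known tree construction
# ---------------------------------------------------------------------------

def best_known_tree(state: TPState, edge: EdgeKey) -> Tree:
    """The tree grown from `edge` by recursively applying the choice maps.

    Starting from the single given edge, leafward choices fill in missing
    children and rootward choices fill in missing parent+sibling pairs,
    until the edge set is a tree on the full taxon set.  Branch lengths are
    the sDAG's stored lengths.
    """
    if not state.sdag.has_edge(edge):
        raise TopPruningError(f"edge not in sDAG: {edge!r}")
    in_tree: set[EdgeKey] = {edge}
    # (node, which) -> chosen child edge, for assembling the topology
    cover: dict[tuple, EdgeKey] = {(edge.parent, edge.which): edge}

    def covered(node, which) -> bool:
        return (node, which) in cover or node.clade(which).is_empty

    def add(k: EdgeKey) -> None:
        slot = (k.parent, k.which)
        if slot not in cover:
            cover[slot] = k
            in_tree.add(k)

    changed = True
    while changed:
        changed = False
        for k in sorted(in_tree):
            entry = state.choice.get(k)
            if not k.child.is_leaf and not (
                covered(k.child, Which.LEFT) and covered(k.child, Which.RIGHT)
            ):
                if entry is None or entry.left is None or entry.right is None:
                    raise TopPruningError(
                        f"leafward choice undefined for edge {k!r}"
                    )
                add(entry.left)
                add(entry.right)
                changed = True
            if not k.parent.is_rho and not any(
                c.child == k.parent for c in in_tree if c != k
            ):
                if entry is None or entry.parent is None or entry.sibling is None:
                    raise TopPruningError(
                        f"rootward choice undefined for edge {k!r}"
                    )
                add(entry.parent)
                add(entry.sibling)
                changed = True

    # assemble the topology from the cover
    taxa = state.sdag.taxa

    def build(node) -> object:
        if node.is_leaf:
            return _leaf(taxa.index(node.left.members[0]))
        kids = []
        for which in (Which.LEFT, Which.RIGHT):
            if node.clade(which).is_empty:
                continue
            kids.append(build(cover[(node, which)].child))
        return _internal(kids[0], kids[1])

    root_edge = cover.get((taxa.rho, Which.RIGHT))
    if root_edge is None:
        raise TopPruningError("choice-map recursion did not reach rho")
    topo = RootedTopology(taxa, build(root_edge.child))
    return tree_from_sdag(state.sdag, topo)


# ---------------------------------------------------------------------------
# Choice-map extension for new edges (argmax strategy)
# ---------------------------------------------------------------------------

def _slot_candidates(state: TPState, k: EdgeKey):
    """Candidate edges for each choice slot of `k`, drawn from the sDAG."""
    d = state.sdag
    rootward = None
    if not k.parent.is_rho:
        parents = d.parents(k.parent)
        siblings = d.children(k.parent, k.which.other)
        rootward = [(p, s) for p in parents for s in siblings]
    left = right = None
    if not k.child.is_leaf:
        left = d.children(k.child, Which.LEFT)
        right = d.children(k.child, Which.RIGHT)
    return rootward, left, right


def _default_entry(state: TPState, k: EdgeKey) -> ChoiceEntry:
    rootward, left, right = _slot_candidates(state, k)
    entry = ChoiceEntry()
    if rootward is not None:
        if not rootward:
            raise TopPruningError(f"no rootward candidate for edge {k!r}")
        entry.parent, entry.sibling = rootward[0]
    if left is not None:
        if not left:
            raise TopPruningError(f"no left-child candidate for edge {k!r}")
        entry.left = left[0]
    if right is not None:
        if not right:
            raise TopPruningError(f"no right-child candidate for edge {k!r}")
        entry.right = right[0]
    return entry


def _argmax_slots(state: TPState, k: EdgeKey) -> None:
    """Greedy per-slot argmax refinement of edge `k`'s choices."""
    rootward, left, right = _slot_candidates(state, k)
    entry = state.choice[k]

    def score() -> float:
        return tree_log_likelihood(best_known_tree(state, k), state.aln)

    if rootward is not None and len(rootward) > 1:
        best = None
        for pair in rootward:
            entry.parent, entry.sibling = pair
            value = score()
            if best is None or value > best[0] + 1e-12:
                best = (value, pair)
        entry.parent, entry.sibling = best[1]
    for slot_name, candidates in (("left", left), ("right", right)):
        if candidates is None or len(candidates) <= 1:
            continue
        best = None
        for cand in candidates:
            setattr(entry, slot_name, cand)
            value = score()
            if best is None or value > best[0] + 1e-12:
                best = (value, cand)
        setattr(entry, slot_name, best[1])


def extend_argmax(
    state: TPState,
    new_edges: Sequence[EdgeKey],
    optimize_lengths: bool = True,
) -> TPState:
    """Assign choices (and optionally lengths) to newly added edges.

    All new edges first receive provisional default choices so that every
    best-known-tree evaluation during the argmax sees fully defined maps;
    each edge's slots are then refined greedily in edge-key order.  With
    `optimize_lengths`, each new edge's branch length is then optimized by
    Brent to maximize the likelihood of its best known tree.  Idempotent
    when `new_edges` is empty.
    """
    new_edges = sorted(new_edges)
    for k in new_edges:
        if k not in state.choice:
            state.choice[k] = _default_entry(state, k)
    for k in new_edges:
        _argmax_slots(state, k)
    if optimize_lengths:
        cfg = state.config.optimizer
        for k in new_edges:
            if k.parent.is_rho:
                continue
            bkt = best_known_tree(state, k)

            def objective(x: float) -> float:
                lengths = dict(bkt.lengths)
                lengths[k] = x
                return tree_log_likelihood(Tree(bkt.topology, lengths), state.aln)

            x_new, _ = brent_maximize(
                objective, cfg.min_branch_length, cfg.max_branch_length,
                cfg.xatol,
            )
            state.sdag.set_branch_length(k, x_new)
    return state


# ---------------------------------------------------------------------------
# The top-pruning likelihood of an NNI
# ---------------------------------------------------------------------------

def tp_likelihood(
    state: TPState, p: NNIProposal, aln: Optional[Alignment] = None
) -> float:
    """Log likelihood of the best known tree for the NNI's central edge.

    Evaluated against a scratch overlay of the post-NNI sDAG: the class
    (a)/(b)/(c) edges inherit the branch lengths of their pre-NNI
    counterpart edges (completion extras get the configured default), the
    central edge's choice slots are argmax-extended, and the central
    edge's branch length is optimized while all others stay fixed.
    """
    aln = aln if aln is not None else state.aln
    overlay, new_edges, counterparts = apply_nni_detailed(
        state.sdag, p, completion="around_new_nodes"
    )
    cfg = state.config
    for k in new_edges:
        src = counterparts.get(k)
        length = (
            state.sdag.branch_length(src) if src is not None
            else cfg.default_branch_length
        )
        if length is None:
            length = cfg.default_branch_length
        overlay.set_branch_length(k, length)
    scratch = TPState(
        overlay, dict(state.choice), aln, cfg,
        edge_first_tree=state.edge_first_tree,
    )
    for k in sorted(new_edges):
        if k not in scratch.choice:
            scratch.choice[k] = _default_entry(scratch, k)
    _argmax_slots(scratch, p.central)

    bkt = best_known_tree(scratch, p.central)
    opt = cfg.optimizer
    to_optimize = [p.central]
    if cfg.optimize_all_new_edges:
        to_optimize = [
            k for k in sorted(set(new_edges) & bkt.topology.edge_keys())
            if not k.parent.is_rho
        ]
    lengths = dict(bkt.lengths)
    value = None
    for k in to_optimize:
        def objective(x: float, _k=k) -> float:
            trial = dict(lengths)
            trial[_k] = x
            return tree_log_likelihood(Tree(bkt.topology, trial), aln)

        x_new, value = brent_maximize(
            objective, opt.min_branch_length, opt.max_branch_length, opt.xatol
        )
        lengths[k] = x_new
    if value is None:
        value = tree_log_likelihood(Tree(bkt.topology, lengths), aln)
    return value


# ---------------------------------------------------------------------------
# The search
# ---------------------------------------------------------------------------

@dataclass
class StopRule:
    """Run for at most `max_iterations`, or until every queued NNI scores
    below `likelihood_threshold` (log scale)."""

    max_iterations: int
    likelihood_threshold: float = -math.inf


@dataclass
class TPSearchResult:
    state: TPState
    trace: list[TPIteration]

    @property
    def sdag(self) -> SubsplitDAG:
        return self.state.sdag


def _queue_insert(queue: list[QueueEntry], entry: QueueEntry) -> None:
    """Keep the queue sorted by (descending score, central edge key)."""
    queue.append(entry)
    queue.sort(key=lambda e: (-e.log_likelihood, e.proposal.central))


def tp_search(
    trees: Sequence[Tree],
    aln: Alignment,
    stop: StopRule,
    config: Optional[SearchConfig] = None,
) -> TPSearchResult:
    """The top-pruning systematic search.

    Each iteration pops the highest-scoring NNI, enlarges the DAG with it
    (full edge completion), extends choice maps and optimizes the new
    branch lengths, then scores and inserts the newly enabled NNIs.
    Scores already in the queue are never refreshed, so pop order can rest
    on values computed against an earlier DAG -- the price of never
    re-evaluating.  Entries that stop being enlarging (their content was
    absorbed by a later completion) are discarded at pop time.
    """
    state = init_from_tree_list(trees, aln, config)
    seen: set[EdgeKey] = set()
    for p in candidate_nnis(state.sdag):
        _queue_insert(state.queue, QueueEntry(tp_likelihood(state, p), p))
        seen.add(p.central)

    trace: list[TPIteration] = []
    iteration = 0
    while iteration < stop.max_iterations:
        while state.queue and not proposal_is_enlarging(
            state.sdag, state.queue[0].proposal
        ):
            state.queue.pop(0)
        if not state.queue:
            break
        if state.queue[0].log_likelihood < stop.likelihood_threshold:
            break
        entry = state.queue.pop(0)
        p = entry.proposal
        iteration += 1

        dag, new_edges, counterparts = apply_nni_detailed(
            state.sdag, p, completion="full"
        )
        for k in new_edges:
            src = counterparts.get(k)
            length = (
                state.sdag.branch_length(src) if src is not None
                else state.config.default_branch_length
            )
            if length is None:
                length = state.config.default_branch_length
            dag.set_branch_length(k, length)
        state.sdag = dag
        extend_argmax(state, new_edges)

        trace.append(TPIteration(
            iteration, p.central, entry.log_likelihood,
            dag.n_nodes, dag.n_edges, count_topologies(dag),
        ))

        for q in candidate_nnis(state.sdag):
            if q.central in seen:
                continue
            seen.add(q.central)
            _queue_insert(state.queue, QueueEntry(tp_likelihood(state, q), q))
    return TPSearchResult(state, trace)
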