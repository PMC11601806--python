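"""Nearest-neighbor-interchange operations that enlarge a subsplit DAG.

On a single topology an NNI swaps two subtrees adjacent to an internal
edge.  On a subsplit DAG the analogous operation *enlarges* the graph: for
a source edge (t, w) -> s with t = {X∪Y, Z} and s = {X, Y}, swapping Y with
Z introduces the subsplits t' = {X∪Z, Y} and s' = {X, Z}; swapping X with Z
introduces t' = {Y∪Z, X} and s' = {Y, Z}.  The pre-NNI DAG is combined with
the rearranged structure by adding

  (a) the *central edge* t' -> s',
  (b) a parent edge u -> t' for every existing u -> t, and
  (c) child edges mirroring the descendants of the affected clades:
      (s', X) -> u for every (s, X) -> u, (t', Y) -> u for every
      (s, Y) -> u, and (s', Z) -> u for every (t, Z) -> u
      (with X/Y exchanged for the other swap),

leaving every other part of the DAG untouched.  New edges carry the
branch-length sentinel; each also has a natural pre-NNI *counterpart* edge
(the one it mirrors), which callers use to seed branch lengths.

When the pre-NNI DAG is edge-complete, every topology new to the post-NNI
DAG contains the central edge and is exactly one NNI away from some
pre-NNI topology; the searches rely on both properties.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

from .sdag import SdagError, SubsplitDAG, complete_edges, completion_edges_touching
from .subsplits import Subsplit, Which, make_subsplit
from .treeio import EdgeKey

CompletionPolicy = Literal["full", "around_new_nodes", "none"]


@dataclass(frozen=True)
class NNIProposal:
    """One NNI of an sDAG: a source edge plus which clade of s swaps with Z.

    `swap` names the clade of the child subsplit s that is exchanged with
    the sibling clade Z of the parent; the other clade of s stays put.
    """

    source: EdgeKey
    swap: Which
    tprime: Subsplit
    sprime: Subsplit
    central: EdgeKey

    @property
    def swapped_clade(self):
        return self.source.child.clade(self.swap)

    def __repr__(self) -> str:
        return f"NNI(source={self.source!r}, swap={self.swap}, central={self.central!r})"


def edge_is_nni_eligible(key: EdgeKey) -> bool:
    """True for edges whose parent is not rho and whose child is internal.

    Edges into leaves have no subsplit to swap; rho has no sibling clade.
    """
    return not key.parent.is_rho and key.child.is_internal


def proposals_for_edge(key: EdgeKey) -> list[NNIProposal]:
    """The two NNI proposals of an eligible edge (swap right, then left)."""
    if not edge_is_nni_eligible(key):
        raise SdagError(f"edge is not NNI-eligible: {key!r}")
    t, w, s = key
    z = t.sibling_clade(w)
    out = []
    for swap in (Which.RIGHT, Which.LEFT):
        moved = s.clade(swap)        # leaves s, becomes t' s other clade
        kept = s.sibling_clade(swap)  # stays in s'
        sprime = make_subsplit(kept, z)
        tprime = make_subsplit(kept | z, moved)
        central = EdgeKey(tprime, tprime.which_clade(sprime.union), sprime)
        out.append(NNIProposal(key, swap, tprime, sprime, central))
    return out


def nni_edge_map(
    d: SubsplitDAG, p: NNIProposal
) -> dict[EdgeKey, EdgeKey]:
    """Class (a)/(b)/(c) edges of the NNI, mapped to their pre-NNI
    counterpart edges in `d` (the central edge's counterpart is the source
    edge)."""
    t, w, s = p.source
    if not d.has_edge(p.source):
        raise SdagError(f"proposal's source edge absent from sDAG: {p.source!r}")
    z = t.sibling_clade(w)
    moved = s.clade(p.swap)
    kept = s.sibling_clade(p.swap)
    out: dict[EdgeKey, EdgeKey] = {p.central: p.source}
    # (b) parents of t': u -> t' for all u -> t
    for pe in d.parents(t):
        out[EdgeKey(pe.parent, pe.which, p.tprime)] = pe
    # (c) descendants of the rearranged clades
    for ce in d.children(s, s.which_clade(kept)):
        out[EdgeKey(p.sprime, p.sprime.which_clade(kept), ce.child)] = ce
    for ce in d.children(s, s.which_clade(moved)):
        out[EdgeKey(p.tprime, p.tprime.which_clade(moved), ce.child)] = ce
    for ce in d.children(t, w.other):
        out[EdgeKey(p.sprime, p.sprime.which_clade(z), ce.child)] = ce
    return out


def proposal_is_enlarging(d: SubsplitDAG, p: NNIProposal) -> bool:
    """True iff applying the proposal would add at least one node or edge."""
    if not (d.has_node(p.tprime) and d.has_node(p.sprime)):
        return True
    return any(not d.has_edge(k) for k in nni_edge_map(d, p))


def candidate_nnis(
    d: SubsplitDAG,
    only_enlarging: bool = True,
    dedupe: bool = True,
) -> list[NNIProposal]:
    """All NNI proposals of the sDAG: two per eligible edge.

    Deduplicated by central edge (the first-generated proposal is kept, in
    source-edge order) and filtered to proposals that enlarge the sDAG,
    unless disabled.
    """
    out: list[NNIProposal] = []
    seen: set[EdgeKey] = set()
    for key in d.edges():
        if not edge_is_nni_eligible(key):
            continue
        for p in proposals_for_edge(key):
            if dedupe:
                if p.central in seen:
                    continue
                seen.add(p.central)
            if only_enlarging and not proposal_is_enlarging(d, p):
                continue
            out.append(p)
    return out


def apply_nni(
    d: SubsplitDAG,
    p: NNIProposal,
    completion: CompletionPolicy = "full",
) -> SubsplitDAG:
    """Enlarged copy of `d` after applying the NNI.

    Pre-NNI content is untouched; all new edges carry the sentinel length.
    `completion` controls which compatible edges are added afterwards:
    "full" runs global edge completion (the top-pruning policy), while
    "around_new_nodes" adds only compatible edges touching t' or s' (the
    generalized-pruning policy).
    """
    out, _, _ = apply_nni_detailed(d, p, completion)
    return out


def apply_nni_detailed(
    d: SubsplitDAG,
    p: NNIProposal,
    completion: CompletionPolicy = "full",
) -> tuple[SubsplitDAG, list[EdgeKey], dict[EdgeKey, EdgeKey]]:
    """As :func:`apply_nni`, also reporting the added edges and the
    counterpart map for class (a)/(b)/(c) edges (completion extras have no
    counterpart and do not appear in the map)."""
    counterparts = nni_edge_map(d, p)
    out = d.copy()
    added: list[EdgeKey] = []
    for key in sorted(counterparts):
        if out.add_edge(key):
            added.append(key)
    if completion == "full":
        before = out.edge_keys()
        out, _ = complete_edges(out, in_place=True)
        added.extend(sorted(out.edge_keys() - before))
    elif completion == "around_new_nodes":
        for key in completion_edges_touching(out, (p.tprime, p.sprime)):
            if out.add_edge(key):
                added.append(key)
    elif completion != "none":
        raise SdagError(f"unknown completion policy: {completion!r}")
    return out, added, counterparts
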