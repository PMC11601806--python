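"""The subsplit DAG: a compact representation of sets of rooted topologies.

Nodes are subsplits (including the universal ancestor rho and one leaf
subsplit per taxon); a directed edge connects a parent subsplit to a child
subsplit that partitions one designated parent clade.  Any tree-structured
subgraph containing all leaves is a rooted topology, so a subsplit DAG built
as the union of several topologies may contain additional topologies beyond
its inputs -- the combinatorial generosity that the search algorithms in
this package exploit.

Edges carry a single branch length each, giving a one-to-one correspondence
between topologies in the DAG and trees in the DAG.  Edges added by
structural operations (completion, NNIs) initially carry a ``None`` sentinel;
likelihood code raises if it touches a sentinel, so callers must assign
lengths before evaluating.  Edges out of rho always have length 0.

Acyclicity is automatic: every edge strictly decreases the taxon-set union
of the node, so no validation pass is needed for cycles.
"""

from __future__ import annotations

import itertools
from typing import Iterable, Iterator, Optional, Sequence

from .subsplits import (
    Clade,
    Subsplit,
    SubsplitError,
    TaxonSet,
    Which,
    is_valid_child,
)
from .treeio import EdgeKey, RootedTopology, Tree, _internal, _leaf

SENTINEL = None  # branch length "unset" marker for freshly added edges


class SdagError(ValueError):
    pass


class SubsplitDAG:
    """Mutable subsplit DAG keyed by (parent subsplit, clade, child subsplit)."""

    def __init__(self, taxa: TaxonSet):
        self.taxa = taxa
        self._lengths: dict[EdgeKey, Optional[float]] = {}
        self._children: dict[tuple[Subsplit, Which], list[Subsplit]] = {}
        self._parents: dict[Subsplit, list[tuple[Subsplit, Which]]] = {}

    # -- basic queries ------------------------------------------------------

    @property
    def n_edges(self) -> int:
        return len(self._lengths)

    @property
    def nodes(self) -> list[Subsplit]:
        """All nodes in subsplit order (derived from the edge set)."""
        seen: set[Subsplit] = set()
        for parent, _, child in self._lengths:
            seen.add(parent)
            seen.add(child)
        return sorted(seen)

    @property
    def n_nodes(self) -> int:
        return len(set(itertools.chain.from_iterable(
            (k.parent, k.child) for k in self._lengths)))

    def has_node(self, node: Subsplit) -> bool:
        if self._parents.get(node):
            return True
        return bool(
            self._children.get((node, Which.LEFT))
            or self._children.get((node, Which.RIGHT))
        )

    def has_edge(self, key: EdgeKey) -> bool:
        return key in self._lengths

    def edges(self) -> list[EdgeKey]:
        return sorted(self._lengths)

    def edge_keys(self) -> frozenset[EdgeKey]:
        return frozenset(self._lengths)

    def children(self, node: Subsplit, which: Which) -> list[EdgeKey]:
        """Outgoing edges of (node, clade), sorted by child subsplit."""
        return [
            EdgeKey(node, which, c)
            for c in sorted(self._children.get((node, which), []))
        ]

    def parents(self, node: Subsplit) -> list[EdgeKey]:
        """Incoming edges of a node, sorted by (parent, which)."""
        return [
            EdgeKey(p, w, node)
            for p, w in sorted(self._parents.get(node, []))
        ]

    def branch_length(self, key: EdgeKey) -> Optional[float]:
        try:
            return self._lengths[key]
        except KeyError:
            raise SdagError(f"edge not in sDAG: {key!r}") from None

    def set_branch_length(self, key: EdgeKey, value: float) -> None:
        if key not in self._lengths:
            raise SdagError(f"edge not in sDAG: {key!r}")
        if key.parent.is_rho:
            value = 0.0
        self._lengths[key] = value

    # -- mutation -----------------------------------------------------------

    def add_edge(self, key: EdgeKey, length: Optional[float] = SENTINEL) -> bool:
        """Insert an edge; returns True if it was new.

        An existing edge's stored branch length is left untouched.  Edges
        out of rho are pinned to length 0.
        """
        parent, which, child = key
        if parent.taxa != self.taxa:
            raise SdagError("edge taxa do not match the sDAG's taxon set")
        if not is_valid_child(parent, which, child):
            raise SdagError(f"invalid edge: {key!r}")
        if key in self._lengths:
            return False
        self._lengths[key] = 0.0 if parent.is_rho else length
        self._children.setdefault((parent, which), []).append(child)
        self._parents.setdefault(child, []).append((parent, which))
        return True

    def copy(self) -> "SubsplitDAG":
        out = SubsplitDAG(self.taxa)
        out._lengths = dict(self._lengths)
        out._children = {k: list(v) for k, v in self._children.items()}
        out._parents = {k: list(v) for k, v in self._parents.items()}
        return out

    # -- invariants ---------------------------------------------------------

    def validate(self) -> None:
        """Check reachability, leaf presence, and outdegree invariants."""
        rho = self.taxa.rho
        roots = self.children(rho, Which.RIGHT)
        if not roots:
            raise SdagError("no edge out of the universal ancestor")
        reached: set[Subsplit] = {rho}
        stack = [k.child for k in roots]
        while stack:
            node = stack.pop()
            if node in reached:
                continue
            reached.add(node)
            if node.is_leaf:
                continue
            for which in (Which.LEFT, Which.RIGHT):
                clade = node.clade(which)
                kids = self.children(node, which)
                if clade.is_empty:
                    if kids:
                        raise SdagError(f"edges out of empty clade of {node!r}")
                    continue
                if not kids:
                    raise SdagError(
                        f"clade {clade!r} of {node!r} has no outgoing edge"
                    )
                stack.extend(k.child for k in kids)
        for node in self.nodes:
            if node not in reached:
                raise SdagError(f"node unreachable from rho: {node!r}")
        for lab in self.taxa.labels:
            if self.taxa.leaf_subsplit(lab) not in reached:
                raise SdagError(f"leaf {lab!r} missing from sDAG")


# ---------------------------------------------------------------------------
# Construction
# ---------------------------------------------------------------------------

def sdag_from_topologies(topologies: Sequence[RootedTopology]) -> SubsplitDAG:
    """Union of the single-topology sDAGs of the inputs.

    Branch lengths are left unset (sentinel) except for rho edges.
    """
    if not topologies:
        raise SdagError("at least one topology is required")
    taxa = topologies[0].taxa
    d = SubsplitDAG(taxa)
    for topo in topologies:
        if topo.taxa != taxa:
            raise SdagError("topologies are on different taxon sets")
        for key in topo.edge_keys():
            d.add_edge(key)
    return d


def sdag_from_trees(
    trees: Sequence[Tree],
) -> tuple[SubsplitDAG, dict[EdgeKey, int]]:
    """Union sDAG with each edge's branch length from the *first* listed tree
    containing it.

    Returns the DAG and a map from edge key to the index of that first tree
    (the edge's "label" in the sense of the choice-map initialization).
    """
    if not trees:
        raise SdagError("at least one tree is required")
    taxa = trees[0].taxa
    d = SubsplitDAG(taxa)
    first: dict[EdgeKey, int] = {}
    for i, tree in enumerate(trees):
        if tree.taxa != taxa:
            raise SdagError("trees are on different taxon sets")
        for key, length in tree.lengths.items():
            if d.add_edge(key, length):
                first[key] = i
    return d, first


# ---------------------------------------------------------------------------
# Completion
# ---------------------------------------------------------------------------

def complete_edges(
    d: SubsplitDAG, in_place: bool = False
) -> tuple[SubsplitDAG, int]:
    """Add an edge for every compatible (parent, clade, child) node triple.

    Added edges carry the branch-length sentinel.  Idempotent: a second
    application adds zero edges.
    """
    out = d if in_place else d.copy()
    nodes = out.nodes
    by_union: dict[int, list[Subsplit]] = {}
    for node in nodes:
        by_union.setdefault(node.union.mask, []).append(node)
    added = 0
    for parent in nodes:
        if parent.is_leaf:
            continue
        for which in (Which.LEFT, Which.RIGHT):
            clade = parent.clade(which)
            if clade.is_empty:
                continue
            for child in by_union.get(clade.mask, []):
                if not is_valid_child(parent, which, child):
                    continue
                if out.add_edge(EdgeKey(parent, which, child)):
                    added += 1
    return out, added


def completion_edges_touching(
    d: SubsplitDAG, focal: Iterable[Subsplit]
) -> list[EdgeKey]:
    """Compatible-but-absent edges with a focal node as parent or child."""
    focal = set(focal)
    nodes = d.nodes
    missing: list[EdgeKey] = []
    for parent in nodes:
        for which in (Which.LEFT, Which.RIGHT):
            clade = parent.clade(which)
            if clade.is_empty:
                continue
            for child in nodes:
                if parent not in focal and child not in focal:
                    continue
                if is_valid_child(parent, which, child):
                    key = EdgeKey(parent, which, child)
                    if not d.has_edge(key):
                        missing.append(key)
    return sorted(set(missing))


# ---------------------------------------------------------------------------
# Topology counting / enumeration / membership
# ---------------------------------------------------------------------------

def count_topologies(d: SubsplitDAG) -> int:
    """Number of distinct topologies in the sDAG, by dynamic programming.

    n(s) is the product over s's nonempty clades of the sum of n over the
    clade's children; leaves contribute 1 and empty clades contribute a
    factor of 1.  The total is n evaluated at rho.
    """
    memo: dict[Subsplit, int] = {}

    def n(node: Subsplit) -> int:
        if node in memo:
            return memo[node]
        if node.is_leaf:
            memo[node] = 1
            return 1
        total = 1
        for which in (Which.LEFT, Which.RIGHT):
            if node.clade(which).is_empty:
                continue
            total *= sum(n(k.child) for k in d.children(node, which))
        memo[node] = total
        return total

    return n(d.taxa.rho)


def enumerate_topologies(
    d: SubsplitDAG, limit: Optional[int] = None
) -> list[RootedTopology]:
    """Distinct topologies of the sDAG in deterministic (lexicographic by
    chosen edges) order, truncated at `limit` if given."""

    def subtrees(node: Subsplit) -> Iterator:
        # yields treeio node structures for the subtree rooted at `node`
        if node.is_leaf:
            yield _leaf(d.taxa.index(node.left.members[0]))
            return
        sides = []
        for which in (Which.LEFT, Which.RIGHT):
            if node.clade(which).is_empty:
                sides.append(None)
            else:
                sides.append([k.child for k in d.children(node, which)])
        if sides[0] is None:
            for child in sides[1]:
                yield from subtrees(child)
            return
        for left_child in sides[0]:
            for left_tree in subtrees(left_child):
                for right_child in sides[1]:
                    for right_tree in subtrees(right_child):
                        yield _internal(left_tree, right_tree)

    out: list[RootedTopology] = []
    for root in subtrees(d.taxa.rho):
        out.append(RootedTopology(d.taxa, root))
        if limit is not None and len(out) >= limit:
            break
    return out


def contains_topology(d: SubsplitDAG, topo: RootedTopology) -> bool:
    """True iff every edge of the topology's sDAG representation is in `d`."""
    if topo.taxa != d.taxa:
        raise SdagError("topology taxa do not match the sDAG's taxon set")
    return all(d.has_edge(k) for k in topo.edge_keys())


def tree_from_sdag(d: SubsplitDAG, topo: RootedTopology) -> Tree:
    """The tree for a topology of the sDAG, using the sDAG's stored lengths."""
    if not contains_topology(d, topo):
        raise SdagError("topology is not contained in the sDAG")
    lengths = {}
    for k in topo.edge_keys():
        v = d.branch_length(k)
        if v is SENTINEL:
            raise SdagError(f"unset (sentinel) branch length on {k!r}")
        lengths[k] = v
    return Tree(topo, lengths)


# ---------------------------------------------------------------------------
# Serialization: one edge per line,
#   parent_subsplit <TAB> which <TAB> child_subsplit <TAB> branch_length
# with subsplits printed as leftmembers|rightmembers (comma separated in
# universe order) and unset lengths printed as NA.  Round-trips bit exactly.
# ---------------------------------------------------------------------------

def _format_subsplit(s: Subsplit) -> str:
    return ",".join(s.left.members) + "|" + ",".join(s.right.members)


def _parse_subsplit(text: str, taxa: TaxonSet) -> Subsplit:
    try:
        left_txt, right_txt = text.split("|")
    except ValueError:
        raise SdagError(f"malformed subsplit field: {text!r}") from None
    left = taxa.clade([x for x in left_txt.split(",") if x])
    right = taxa.clade([x for x in right_txt.split(",") if x])
    return Subsplit(left, right)


def sdag_to_text(d: SubsplitDAG) -> str:
    lines = []
    for key in d.edges():
        length = d._lengths[key]
        length_txt = "NA" if length is SENTINEL else repr(length)
        lines.append(
            f"{_format_subsplit(key.parent)}\t{key.which}\t"
            f"{_format_subsplit(key.child)}\t{length_txt}"
        )
    return "\n".join(lines) + "\n"


def sdag_from_text(text: str, taxa: Optional[TaxonSet] = None) -> SubsplitDAG:
    rows = [line.split("\t") for line in text.splitlines() if line.strip()]
    if taxa is None:
        # the rho line lists every taxon, in universe order, on its right side
        for row in rows:
            left_txt, right_txt = row[0].split("|")
            if not left_txt:
                taxa = TaxonSet(tuple(right_txt.split(",")))
                break
        else:
            raise SdagError("cannot infer taxa: no rho edge in input")
    d = SubsplitDAG(taxa)
    for row in rows:
        if len(row) != 4:
            raise SdagError(f"malformed edge line: {row!r}")
        parent = _parse_subsplit(row[0], taxa)
        which = Which(row[1])
        child = _parse_subsplit(row[2], taxa)
        length = SENTINEL if row[3] == "NA" else float(row[3])
        d.add_edge(EdgeKey(parent, which, child), length)
    return d
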