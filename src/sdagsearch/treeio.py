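"""Rooted bifurcating topologies, trees, and Newick input/output.

A :class:`RootedTopology` is an immutable recursive structure over a
:class:`~sdagsearch.subsplits.TaxonSet`; every internal node has exactly two
children and corresponds to a unique subsplit, so a topology is equivalently
the set of its subsplit-DAG edges (including the edge from the universal
ancestor rho to the root split).  A :class:`Tree` adds one nonnegative branch
length per edge; the rho edge always carries length 0 and is excluded from
likelihood products.

The Newick dialect is deliberately narrow: rooted, strictly bifurcating,
bare or single-quoted labels, optional branch lengths, mandatory semicolon,
no comments.  Written strings are canonical -- children of every node are
ordered by the clade order -- so parse∘write is the identity on canonical
strings and write∘parse canonicalizes arbitrary valid input.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Optional

from .subsplits import (
    Clade,
    Subsplit,
    SubsplitError,
    TaxonSet,
    Which,
    make_subsplit,
)


class NewickError(ValueError):
    """Malformed Newick input; the message includes a character position."""


class EdgeKey(NamedTuple):
    """Identity of a subsplit-DAG edge: (parent, partitioned clade, child)."""

    parent: Subsplit
    which: Which
    child: Subsplit

    def __repr__(self) -> str:
        return f"({self.parent!r},{self.which})->{self.child!r}"


@dataclass(frozen=True)
class _Node:
    """A node of a rooted topology; leaf iff ``children is None``."""

    mask: int
    taxon: Optional[int]
    children: Optional[tuple["_Node", "_Node"]]


def _mask_lt(a: int, b: int) -> bool:
    # clade order on raw masks: member of the first differing taxon first
    if a == b:
        return False
    diff = a ^ b
    return bool(a & (diff & -diff))


def _leaf(i: int) -> _Node:
    return _Node(1 << i, i, None)


def _internal(a: _Node, b: _Node) -> _Node:
    if a.mask & b.mask:
        raise SubsplitError("child clades overlap")
    if _mask_lt(b.mask, a.mask):
        a, b = b, a
    return _Node(a.mask | b.mask, None, (a, b))


class RootedTopology:
    """An immutable rooted bifurcating topology on a taxon set."""

    __slots__ = ("taxa", "root", "_edge_keys", "_hash")

    def __init__(self, taxa: TaxonSet, root: _Node):
        if root.mask != (1 << taxa.n) - 1:
            raise SubsplitError("topology must cover the full taxon set")
        self.taxa = taxa
        self.root = root
        self._edge_keys: Optional[frozenset[EdgeKey]] = None
        self._hash: Optional[int] = None

    # -- structure ----------------------------------------------------------

    def node_subsplit(self, node: _Node) -> Subsplit:
        if node.children is None:
            return Subsplit(
                Clade(self.taxa, node.mask), self.taxa.empty_clade
            )
        a, b = node.children
        return make_subsplit(Clade(self.taxa, a.mask), Clade(self.taxa, b.mask))

    def edge_keys(self) -> frozenset[EdgeKey]:
        """The 2n-1 subsplit-DAG edges of this topology, rho edge included."""
        if self._edge_keys is None:
            keys: list[EdgeKey] = []
            rho = self.taxa.rho
            root_sub = self.node_subsplit(self.root)
            keys.append(EdgeKey(rho, Which.RIGHT, root_sub))

            def walk(node: _Node, sub: Subsplit) -> None:
                if node.children is None:
                    return
                for child in node.children:
                    csub = self.node_subsplit(child)
                    which = sub.which_clade(Clade(self.taxa, child.mask))
                    keys.append(EdgeKey(sub, which, csub))
                    walk(child, csub)

            walk(self.root, root_sub)
            self._edge_keys = frozenset(keys)
        return self._edge_keys

    def subsplits(self) -> frozenset[Subsplit]:
        """All subsplits of the topology (leaves included, rho excluded)."""
        return frozenset(k.child for k in self.edge_keys())

    def newick(self) -> str:
        return write_newick_topology(self)

    # -- identity -----------------------------------------------------------

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RootedTopology):
            return NotImplemented
        return self.taxa == other.taxa and self.edge_keys() == other.edge_keys()

    def __hash__(self) -> int:
        if self._hash is None:
            self._hash = hash((self.taxa, self.edge_keys()))
        return self._hash

    def __lt__(self, other: "RootedTopology") -> bool:
        return self.newick() < other.newick()

    def __repr__(self) -> str:
        return f"RootedTopology({self.newick()!r})"


@dataclass(frozen=True)
class Tree:
    """A topology with one branch length per edge (rho edge fixed at 0)."""

    topology: RootedTopology
    lengths: dict[EdgeKey, float]

    def __post_init__(self) -> None:
        keys = self.topology.edge_keys()
        missing = keys - set(self.lengths)
        if missing:
            raise SubsplitError(f"missing branch lengths for {sorted(missing)}")
        rho_edge = next(k for k in keys if k.parent.is_rho)
        fixed = dict(self.lengths)
        fixed[rho_edge] = 0.0
        for k, v in fixed.items():
            if v < 0:
                raise SubsplitError(f"negative branch length on {k!r}")
        object.__setattr__(self, "lengths", fixed)

    @property
    def taxa(self) -> TaxonSet:
        return self.topology.taxa

    def newick(self) -> str:
        return write_newick(self)


def topology_from_newick_structure(
    taxa: TaxonSet, structure
) -> RootedTopology:
    """Build a topology from nested pairs of labels, e.g. ``("0", ("1", "2"))``."""

    def build(s) -> _Node:
        if isinstance(s, str):
            return _leaf(taxa.index(s))
        if len(s) != 2:
            raise SubsplitError("internal nodes must have exactly 2 children")
        return _internal(build(s[0]), build(s[1]))

    return RootedTopology(taxa, build(structure))


# ---------------------------------------------------------------------------
# Newick parsing
# ---------------------------------------------------------------------------

_BARE_LABEL = re.compile(r"[^\s()\[\],:;']+")
_NUMBER = re.compile(r"[-+]?\d*\.?\d+([eE][-+]?\d+)?")


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.pos = 0

    def error(self, msg: str):
        raise NewickError(f"{msg} at position {self.pos}")

    def skip_ws(self) -> None:
        while self.pos < len(self.text) and self.text[self.pos].isspace():
            self.pos += 1

    def peek(self) -> str:
        self.skip_ws()
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def expect(self, ch: str) -> None:
        if self.peek() != ch:
            self.error(f"expected {ch!r}")
        self.pos += 1

    def label(self) -> str:
        self.skip_ws()
        if self.peek() == "'":
            end = self.text.find("'", self.pos + 1)
            if end < 0:
                self.error("unterminated quoted label")
            lab = self.text[self.pos + 1 : end]
            self.pos = end + 1
            return lab
        m = _BARE_LABEL.match(self.text, self.pos)
        if not m:
            self.error("expected a taxon label")
        self.pos = m.end()
        return m.group()

    def length(self) -> Optional[float]:
        if self.peek() != ":":
            return None
        self.pos += 1
        self.skip_ws()
        m = _NUMBER.match(self.text, self.pos)
        if not m:
            self.error("expected a branch length")
        self.pos = m.end()
        return float(m.group())

    def subtree(self):
        """Returns (structure, length) with structure a label or 2-tuple."""
        if self.peek() == "(":
            self.pos += 1
            children = [self.subtree()]
            while self.peek() == ",":
                self.pos += 1
                children.append(self.subtree())
            self.expect(")")
            if len(children) != 2:
                self.error(
                    f"node with {len(children)} children; trees must be "
                    "strictly bifurcating"
                )
            # internal node label, ignored on read
            if self.peek() not in (":", ",", ")", ";", ""):
                self.label()
            ln = self.length()
            return (children[0], children[1]), ln
        lab = self.label()
        ln = self.length()
        return lab, ln


def parse_newick(text: str, taxa: Optional[TaxonSet] = None) -> Tree:
    """Parse a rooted bifurcating Newick string into a :class:`Tree`.

    Branch lengths default to 0 where absent.  When `taxa` is not supplied
    the taxon set is inferred as the sorted set of leaf labels.  A length on
    the root node is ignored (the rho edge has length 0 by construction).
    """
    parser = _Parser(text)
    structure, _root_len = parser.subtree()
    parser.expect(";")
    parser.skip_ws()
    if parser.pos != len(text):
        parser.error("trailing characters after ';'")

    # structure is nested ((struct, len), (struct, len)) pairs at internal
    # nodes and (label, len) at leaves
    stripped = (structure, _root_len)

    labels: list[str] = []

    def collect(s) -> None:
        node, _ = s
        if isinstance(node, str):
            labels.append(node)
        else:
            collect(node[0])
            collect(node[1])

    collect(stripped)
    dupes = sorted({x for x in labels if labels.count(x) > 1})
    if dupes:
        raise NewickError(f"duplicate taxa: {dupes}")
    if taxa is None:
        taxa = TaxonSet(tuple(sorted(labels)))
    else:
        for lab in labels:
            taxa.index(lab)  # raises on unknown label
        if len(labels) != taxa.n:
            missing = sorted(set(taxa.labels) - set(labels))
            raise NewickError(f"taxa absent from tree: {missing}")

    lengths: dict[int, float] = {}  # child clade mask -> length

    def build(s) -> _Node:
        node, ln = s
        if isinstance(node, str):
            built = _leaf(taxa.index(node))
        else:
            built = _internal(build(node[0]), build(node[1]))
        lengths[built.mask] = ln if ln is not None else 0.0
        return built

    root = build(stripped)
    topo = RootedTopology(taxa, root)
    edge_lengths = {
        k: (0.0 if k.parent.is_rho else lengths[k.child.union.mask])
        for k in topo.edge_keys()
    }
    return Tree(topo, edge_lengths)


def parse_newick_topology(
    text: str, taxa: Optional[TaxonSet] = None
) -> RootedTopology:
    return parse_newick(text, taxa).topology


# ---------------------------------------------------------------------------
# Newick writing
# ---------------------------------------------------------------------------

def _format_label(label: str) -> str:
    if _BARE_LABEL.fullmatch(label):
        return label
    return "'" + label + "'"


def _format_length(x: float) -> str:
    return f"{x:.10g}"


def write_newick_topology(topo: RootedTopology) -> str:
    """Canonical topology-only Newick (no branch lengths)."""

    def render(node: _Node) -> str:
        if node.children is None:
            return _format_label(topo.taxa.labels[node.taxon])
        a, b = node.children
        return f"({render(a)},{render(b)})"

    return render(topo.root) + ";"


def write_newick(tree: Tree) -> str:
    """Canonical Newick with branch lengths (omitted when all are zero)."""
    topo = tree.topology
    if all(v == 0.0 for v in tree.lengths.values()):
        return write_newick_topology(topo)
    by_mask = {
        k.child.union.mask: v
        for k, v in tree.lengths.items()
        if not k.parent.is_rho
    }

    def render(node: _Node, is_root: bool) -> str:
        if node.children is None:
            s = _format_label(topo.taxa.labels[node.taxon])
        else:
            a, b = node.children
            s = f"({render(a, False)},{render(b, False)})"
        if not is_root:
            s += ":" + _format_length(by_mask[node.mask])
        return s

    return render(topo.root, True) + ";"


def topology_to_edges(topo: RootedTopology) -> list[EdgeKey]:
    """The sorted edge keys of the single-topology sDAG representation."""
    return sorted(topo.edge_keys())
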