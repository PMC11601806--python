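"""Taxon sets, clades, and subsplits: the algebra underlying the subsplit DAG.

A *clade* is a subset of a fixed, ordered taxon set, represented as a bitmask
over taxon indices.  A *subsplit* is an ordered pair of disjoint clades; it
labels a node of a subsplit DAG and records how the taxa below that node are
bipartitioned.  The taxon order induces a total order on clades (the member
of the first differing taxon sorts first), and the lesser subsplit-clade of a
subsplit is called its *left* clade.

Two degenerate subsplits are permitted: a *leaf* subsplit pairs a singleton
clade with the empty clade, and the *universal ancestor* ``rho`` pairs the
empty clade with the full taxon set (the one sanctioned exception to the
left-before-right canonical order, so that edges out of ``rho`` always
partition its right clade).
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Iterator


class SubsplitError(ValueError):
    """Raised for malformed clades, subsplits, or mismatched taxon sets."""


@dataclass(frozen=True)
class TaxonSet:
    """An ordered collection of distinct taxon labels.

    The order is fixed for the lifetime of every structure built on the
    taxon set; it determines clade comparison and all deterministic
    iteration orders downstream.
    """

    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if not isinstance(self.labels, tuple):
            object.__setattr__(self, "labels", tuple(self.labels))
        if len(set(self.labels)) != len(self.labels):
            dupes = sorted({x for x in self.labels if self.labels.count(x) > 1})
            raise SubsplitError(f"duplicate taxon labels: {dupes}")

    @property
    def n(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise SubsplitError(f"unknown taxon label: {label!r}") from None

    # -- clade constructors -------------------------------------------------

    def clade(self, members: Iterable[str]) -> "Clade":
        return make_clade(members, self)

    @property
    def empty_clade(self) -> "Clade":
        return Clade(self, 0)

    @property
    def full_clade(self) -> "Clade":
        return Clade(self, (1 << self.n) - 1)

    def leaf_subsplit(self, label: str) -> "Subsplit":
        return Subsplit(Clade(self, 1 << self.index(label)), self.empty_clade)

    @property
    def rho(self) -> "Subsplit":
        """The universal ancestor: left = empty clade, right = full clade."""
        return Subsplit(self.empty_clade, self.full_clade)


@functools.total_ordering
@dataclass(frozen=True)
class Clade:
    """A subset of a taxon set, held as a bitmask in taxon order."""

    taxa: TaxonSet
    mask: int

    def __post_init__(self) -> None:
        if self.mask < 0 or self.mask >> self.taxa.n:
            raise SubsplitError("clade mask out of range for its taxon set")

    @property
    def members(self) -> tuple[str, ...]:
        return tuple(
            lab for i, lab in enumerate(self.taxa.labels) if self.mask >> i & 1
        )

    @property
    def is_empty(self) -> bool:
        return self.mask == 0

    @property
    def is_full(self) -> bool:
        return self.mask == (1 << self.taxa.n) - 1

    @property
    def is_singleton(self) -> bool:
        return self.mask != 0 and self.mask & (self.mask - 1) == 0

    def __len__(self) -> int:
        return self.mask.bit_count()

    def __contains__(self, label: str) -> bool:
        return bool(self.mask >> self.taxa.index(label) & 1)

    def __iter__(self) -> Iterator[str]:
        return iter(self.members)

    def __or__(self, other: "Clade") -> "Clade":
        _check_universe(self, other)
        return Clade(self.taxa, self.mask | other.mask)

    def __and__(self, other: "Clade") -> "Clade":
        _check_universe(self, other)
        return Clade(self.taxa, self.mask & other.mask)

    def disjoint(self, other: "Clade") -> bool:
        _check_universe(self, other)
        return self.mask & other.mask == 0

    def __lt__(self, other: "Clade") -> bool:
        return compare_clades(self, other) < 0

    def __repr__(self) -> str:
        return "{" + ",".join(self.members) + "}"


def _check_universe(a, b) -> None:
    if a.taxa != b.taxa:
        raise SubsplitError(
            f"taxon sets differ: {a.taxa.labels} vs {b.taxa.labels}"
        )


def make_clade(members: Iterable[str], universe: TaxonSet) -> Clade:
    """Build the clade of `universe` with exactly the given member labels."""
    seen: set[str] = set()
    mask = 0
    for label in members:
        if label in seen:
            raise SubsplitError(f"duplicate taxon label: {label!r}")
        seen.add(label)
        mask |= 1 << universe.index(label)
    return Clade(universe, mask)


def compare_clades(a: Clade, b: Clade) -> int:
    """Total order on clades extending the taxon order.

    Membership vectors are compared in taxon order; at the first taxon where
    the clades differ, the clade containing it sorts first.  Returns -1, 0,
    or 1.  Notable consequence: every nonempty clade sorts before the empty
    clade.
    """
    _check_universe(a, b)
    if a.mask == b.mask:
        return 0
    diff = a.mask ^ b.mask
    low = diff & -diff
    return -1 if a.mask & low else 1


class Which(str, Enum):
    """Designates one of the two clades of a subsplit."""

    LEFT = "left"
    RIGHT = "right"

    @property
    def other(self) -> "Which":
        return Which.RIGHT if self is Which.LEFT else Which.LEFT

    def __str__(self) -> str:  # serialized form
        return self.value


@functools.total_ordering
@dataclass(frozen=True)
class Subsplit:
    """An ordered pair of disjoint clades labeling a subsplit-DAG node.

    Invariants: left and right are disjoint, their union is nonempty, and
    left sorts before right -- except for rho, which is stored with the
    empty clade on the left so that edges out of rho uniformly partition
    its right clade.  Empty clades occur only in rho and leaf subsplits.
    """

    left: Clade
    right: Clade

    def __post_init__(self) -> None:
        _check_universe(self.left, self.right)
        if self.left.mask & self.right.mask:
            overlap = Clade(self.taxa, self.left.mask & self.right.mask)
            raise SubsplitError(f"subsplit clades overlap on {overlap!r}")
        if self.left.is_empty and self.right.is_empty:
            raise SubsplitError("subsplit must have a nonempty clade")
        if self.left.is_empty:
            if not self.right.is_full:
                raise SubsplitError(
                    "empty left clade is reserved for the universal ancestor"
                )
        elif self.right.is_empty:
            if not self.left.is_singleton:
                raise SubsplitError(
                    "empty right clade is reserved for leaf subsplits"
                )
        elif compare_clades(self.left, self.right) > 0:
            raise SubsplitError(
                f"subsplit clades out of canonical order: {self.left!r} > "
                f"{self.right!r}; use make_subsplit"
            )

    @property
    def taxa(self) -> TaxonSet:
        return self.left.taxa

    @property
    def union(self) -> Clade:
        return Clade(self.taxa, self.left.mask | self.right.mask)

    @property
    def is_rho(self) -> bool:
        return self.left.is_empty

    @property
    def is_leaf(self) -> bool:
        return self.right.is_empty

    @property
    def is_internal(self) -> bool:
        """True iff both clades are nonempty (root splits included)."""
        return not self.left.is_empty and not self.right.is_empty

    def clade(self, which: Which) -> Clade:
        return self.left if which is Which.LEFT else self.right

    def sibling_clade(self, which: Which) -> Clade:
        return self.clade(which.other)

    def which_clade(self, clade: Clade) -> Which:
        """The side of this subsplit whose clade equals `clade`."""
        if clade.mask == self.left.mask:
            return Which.LEFT
        if clade.mask == self.right.mask:
            return Which.RIGHT
        raise SubsplitError(f"{clade!r} is not a clade of {self!r}")

    def _key(self):
        return (self.left.mask, self.right.mask)

    def __lt__(self, other: "Subsplit") -> bool:
        _check_universe(self.left, other.left)
        c = compare_clades(self.left, other.left)
        if c != 0:
            return c < 0
        return compare_clades(self.right, other.right) < 0

    def __repr__(self) -> str:
        return f"{{{self.left!r},{self.right!r}}}"


def make_subsplit(a: Clade, b: Clade) -> Subsplit:
    """Canonical subsplit of two disjoint clades (lesser clade on the left).

    Symmetric in its arguments: ``make_subsplit(a, b) == make_subsplit(b, a)``.
    """
    _check_universe(a, b)
    if a.mask & b.mask:
        overlap = Clade(a.taxa, a.mask & b.mask)
        raise SubsplitError(f"subsplit clades overlap on {overlap!r}")
    if compare_clades(a, b) <= 0:
        return Subsplit(a, b)
    return Subsplit(b, a)


def is_valid_child(parent: Subsplit, which: Which, child: Subsplit) -> bool:
    """True iff `child`'s two clades partition the designated clade of `parent`.

    Degenerate queries return False: an empty designated clade (leaf
    subsplits, the left clade of rho), a leaf subsplit as parent (leaves
    have no children), or rho as child.
    """
    _check_universe(parent.left, child.left)
    if parent.is_leaf or child.is_rho:
        return False
    target = parent.clade(which)
    if target.is_empty:
        return False
    return child.union.mask == target.mask
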