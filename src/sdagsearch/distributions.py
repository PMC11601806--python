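"""Probability distributions on subsplit-DAG edges and posterior coverage.

Assigning a probability vector to the outgoing edges of every
(node, clade) choice point of a subsplit DAG induces a normalized
probability distribution over the topologies in the DAG: a topology's
probability is the product of its edges' conditional probabilities.  This
strictly generalizes conditional clade distributions (CCDs), which force
choice points sharing a clade to share one vector regardless of the
sister clade; :func:`is_clade_conditional` tests for that special case.

Fitting from a topology sample is frequency counting: the probability of a
child subsplit given a (parent, clade) choice point is the fraction of
sampled topologies containing the parent that resolve the clade with that
child.

The evaluation half compares a DAG against an empirical posterior (a
topology -> density table, e.g. from a long MCMC run): total density
covered, minimal credible sets, and the credibility of the DAG's subsplits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .sdag import SdagError, SubsplitDAG, contains_topology
from .simulate import RngLike, as_rng
from .subsplits import Subsplit, TaxonSet, Which
from .treeio import (
    EdgeKey,
    RootedTopology,
    _internal,
    _leaf,
    parse_newick_topology,
)


class DistributionError(ValueError):
    pass


ChoicePoint = tuple[Subsplit, Which]


class EdgeProbabilities:
    """A probability vector over the outgoing edges of each choice point.

    Every (node, clade) pair of the DAG with at least one outgoing edge has
    a vector; vectors are nonnegative and sum to one.
    """

    def __init__(
        self,
        d: SubsplitDAG,
        table: Mapping[ChoicePoint, Mapping[Subsplit, float]],
    ):
        self.d = d
        self.table = {
            point: dict(vector) for point, vector in table.items()
        }
        for point, vector in self.table.items():
            node, which = point
            children = {k.child for k in d.children(node, which)}
            if set(vector) != children:
                raise DistributionError(
                    f"vector support mismatch at {point!r}"
                )
            total = sum(vector.values())
            if any(v < 0 for v in vector.values()) or abs(total - 1) > 1e-12:
                raise DistributionError(
                    f"probabilities at {point!r} sum to {total}, not 1"
                )
        for node in d.nodes:
            if node.is_leaf:
                continue
            for which in (Which.LEFT, Which.RIGHT):
                if node.clade(which).is_empty:
                    continue
                if (node, which) not in self.table:
                    raise DistributionError(
                        f"no probability vector for choice point "
                        f"({node!r}, {which})"
                    )

    @classmethod
    def uniform(cls, d: SubsplitDAG) -> "EdgeProbabilities":
        table = {}
        for node in d.nodes:
            if node.is_leaf:
                continue
            for which in (Which.LEFT, Which.RIGHT):
                kids = d.children(node, which)
                if kids:
                    table[(node, which)] = {
                        k.child: 1.0 / len(kids) for k in kids
                    }
        return cls(d, table)

    def prob(self, key: EdgeKey) -> float:
        return self.table[(key.parent, key.which)][key.child]

    def vector(self, node: Subsplit, which: Which) -> dict[Subsplit, float]:
        return dict(self.table[(node, which)])


def topology_probability(
    d: SubsplitDAG, probs: EdgeProbabilities, topo: RootedTopology
) -> float:
    """Product of the topology's edges' conditional probabilities."""
    if not contains_topology(d, topo):
        raise SdagError("topology is not contained in the sDAG")
    value = 1.0
    for key in topo.edge_keys():
        value *= probs.prob(key)
    return value


def fit_edge_probabilities(
    d: SubsplitDAG, sample: Sequence[RootedTopology]
) -> EdgeProbabilities:
    """Normalized frequency counts of child subsplits in the sample.

    P(child | parent, clade) is the number of sampled topologies containing
    both the parent and that child edge over the number containing the
    parent (with that clade resolved).  Choice points never visited by the
    sample get the uniform vector.
    """
    if not sample:
        raise DistributionError("empty topology sample")
    counts: dict[EdgeKey, int] = {}
    for topo in sample:
        if not contains_topology(d, topo):
            raise SdagError(
                "sampled topology is not contained in the sDAG; add it first"
            )
        for key in topo.edge_keys():
            counts[key] = counts.get(key, 0) + 1
    table = {}
    for node in d.nodes:
        if node.is_leaf:
            continue
        for which in (Which.LEFT, Which.RIGHT):
            kids = d.children(node, which)
            if not kids:
                continue
            per_child = {k.child: counts.get(k, 0) for k in kids}
            total = sum(per_child.values())
            if total == 0:
                table[(node, which)] = {
                    c: 1.0 / len(kids) for c in per_child
                }
            else:
                table[(node, which)] = {
                    c: n / total for c, n in per_child.items()
                }
    return EdgeProbabilities(d, table)


def sample_topologies(
    d: SubsplitDAG,
    probs: EdgeProbabilities,
    n: int,
    rng: RngLike,
) -> list[RootedTopology]:
    """Draw iid topologies from the distribution (root-down sampling)."""
    rng = as_rng(rng)

    def draw(node: Subsplit):
        if node.is_leaf:
            return _leaf(d.taxa.index(node.left.members[0]))
        kids = []
        for which in (Which.LEFT, Which.RIGHT):
            if node.clade(which).is_empty:
                continue
            vector = probs.vector(node, which)
            children = sorted(vector)
            weights = np.array([vector[c] for c in children])
            choice = children[int(rng.choice(len(children), p=weights))]
            kids.append(draw(choice))
        if len(kids) == 1:
            return kids[0]
        return _internal(kids[0], kids[1])

    return [RootedTopology(d.taxa, draw(d.taxa.rho)) for _ in range(n)]


def is_clade_conditional(probs: EdgeProbabilities, tol: float = 1e-12) -> bool:
    """True iff the distribution is a CCD in DAG clothing.

    A conditional clade distribution requires choice points on the same
    clade to carry identical probability vectors; the subsplit DAG permits
    them to differ (conditioning on the sister clade).
    """
    by_clade: dict[int, dict] = {}
    for (node, which), vector in probs.table.items():
        mask = node.clade(which).mask
        keyed = {c: p for c, p in vector.items()}
        if mask in by_clade:
            ref = by_clade[mask]
            if set(ref) != set(keyed):
                return False
            if any(abs(ref[c] - keyed[c]) > tol for c in ref):
                return False
        else:
            by_clade[mask] = keyed
    return True


# ---------------------------------------------------------------------------
# Empirical posteriors and coverage
# ---------------------------------------------------------------------------

@dataclass
class PosteriorTable:
    """Empirical posterior: topology -> density, matched by subsplit-set
    identity (canonicalized on construction), densities summing to <= 1."""

    densities: dict[RootedTopology, float]

    def __post_init__(self) -> None:
        total = sum(self.densities.values())
        if total > 1 + 1e-9:
            raise DistributionError(f"densities sum to {total} > 1")
        if any(v < 0 for v in self.densities.values()):
            raise DistributionError("negative density")

    @property
    def total_density(self) -> float:
        return sum(self.densities.values())

    def __len__(self) -> int:
        return len(self.densities)

    @classmethod
    def from_tsv(
        cls, path, taxa: Optional[TaxonSet] = None
    ) -> "PosteriorTable":
        """Read a headerless `newick<TAB>density` table."""
        frame = pd.read_csv(
            path, sep="\t", header=None, names=["newick", "density"],
            dtype={"newick": str, "density": float},
        )
        densities: dict[RootedTopology, float] = {}
        for row in frame.itertuples(index=False):
            topo = parse_newick_topology(row.newick, taxa)
            if taxa is None:
                taxa = topo.taxa
            if topo in densities:
                raise DistributionError(
                    f"duplicate topology in table: {row.newick}"
                )
            densities[topo] = float(row.density)
        return cls(densities)

    def to_tsv(self, path) -> None:
        rows = sorted(
            self.densities.items(), key=lambda kv: (-kv[1], kv[0].newick())
        )
        frame = pd.DataFrame(
            [(t.newick(), v) for t, v in rows], columns=["newick", "density"]
        )
        frame.to_csv(path, sep="\t", header=False, index=False)


def credible_set(
    post: PosteriorTable, level: float
) -> set[RootedTopology]:
    """Minimal-size set of topologies with cumulative density >= level.

    Topologies are taken in decreasing density order (ties broken by
    canonical Newick string).
    """
    if not 0 < level <= 1:
        raise DistributionError(f"credible level must be in (0, 1]: {level}")
    if post.total_density < level - 1e-12:
        raise DistributionError(
            f"total density {post.total_density:.6g} falls short of the "
            f"requested level {level} by "
            f"{level - post.total_density:.6g}"
        )
    ordered = sorted(
        post.densities.items(), key=lambda kv: (-kv[1], kv[0].newick())
    )
    out: set[RootedTopology] = set()
    cumulative = 0.0
    for topo, density in ordered:
        out.add(topo)
        cumulative += density
        if cumulative >= level - 1e-12:
            break
    return out


def coverage(d: SubsplitDAG, post: PosteriorTable) -> float:
    """Total posterior density of the topologies present in the sDAG."""
    return sum(
        density for topo, density in post.densities.items()
        if topo.taxa == d.taxa and contains_topology(d, topo)
    )


def _internal_subsplits(items: Iterable[Subsplit]) -> set[Subsplit]:
    return {s for s in items if s.is_internal}


def subsplit_credibility(
    d: SubsplitDAG, credible: Iterable[RootedTopology]
) -> tuple[float, float]:
    """How the sDAG's subsplits compare with the credible ones.

    A subsplit is *credible* if it appears in at least one topology of the
    credible set.  Returns (found_fraction, precision): the fraction of
    credible subsplits present in the sDAG, and the fraction of the sDAG's
    subsplits that are credible.  Leaves and rho are excluded from both
    counts.
    """
    credible = list(credible)
    if not credible:
        raise DistributionError("empty credible set")
    credible_subs: set[Subsplit] = set()
    for topo in credible:
        credible_subs |= _internal_subsplits(topo.subsplits())
    dag_subs = _internal_subsplits(d.nodes)
    overlap = credible_subs & dag_subs
    return len(overlap) / len(credible_subs), len(overlap) / len(dag_subs)
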