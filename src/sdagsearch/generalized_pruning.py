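"""Generalized pruning: a per-edge, topology-marginal composite likelihood.

For an edge e of a subsplit DAG with fixed branch lengths, let T_e be the
set of trees in the DAG containing e.  The generalized-pruning (GP)
likelihood of e is the product over alignment sites j of the prior-weighted
average of the per-site tree likelihoods,

    prod_j  sum_{tau in T_e}  p(Y_j | tau) p(tau | e),

a *composite* likelihood: sites are marginalized independently rather than
jointly, which is what makes a shared-PLV dynamic program possible.  Under
the uniform prior used here, p(tau | e) = 1/|T_e|.

The DP shares partial likelihood vectors across all topologies:

* leafward, per node s and clade w:
      phat(s, w)_x = sum_{(s,w)->c} [P(psi_edge) p(c)]_x,
      p(s) = phat(s, left) * phat(s, right)
  with observation indicators at leaves and all-ones for empty clades.
  These are *sums over subtree resolutions*, so the number of accumulated
  terms equals the number of subtrees -- the same recursion, run on counts
  instead of vectors, yields |T_e|;
* rootward, per edge e = (t, w) -> s:
      above(e) = r(t) * phat(t, sibling clade of w),
      r(s) = sum over parent edges e' of P(psi_e')^T above(e'),
  seeded with the stationary 1/4 vector at rho.

The per-site sum over T_e is then  above(e) . P(psi_e) p(s).  Everything is
carried in linear space with per-site log-scale accumulators.

These recursions are validated against a brute-force enumeration oracle
(:func:`gp_likelihood_bruteforce`); the *true* (non-composite) marginal
likelihood, which averages whole-alignment tree likelihoods instead, is
provided for contrast as :func:`true_marginal_bruteforce` and has no
efficient DP.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import logsumexp

from ._config import SearchConfig
from .nni import NNIProposal, apply_nni_detailed, candidate_nnis, proposal_is_enlarging
from .phylo import Alignment, PhyloError, brent_maximize, jc_transition_matrix, tree_log_likelihood
from .sdag import (
    SdagError,
    SubsplitDAG,
    complete_edges,
    count_topologies,
    enumerate_topologies,
    sdag_from_trees,
    tree_from_sdag,
)
from .subsplits import Subsplit, Which
from .treeio import EdgeKey, Tree


def _leafward_order(d: SubsplitDAG) -> list[Subsplit]:
    """Children before parents; rho (tied with root splits on union size)
    explicitly last."""
    return sorted(d.nodes, key=lambda s: (len(s.union), s.is_rho, s))


def _rootward_order(d: SubsplitDAG) -> list[Subsplit]:
    return list(reversed(_leafward_order(d)))


class GPError(ValueError):
    pass


def _scaled(arr: np.ndarray, logscale: np.ndarray):
    """Rescale so each site's max entry is 1; push magnitude into logscale."""
    top = arr.max(axis=1)
    safe = np.where(top > 0, top, 1.0)
    with np.errstate(divide="ignore"):
        return arr / safe[:, None], logscale + np.log(np.where(top > 0, safe, 0.0))


def _scaled_sum(terms):
    """Sum of (array, logscale) pairs with per-site scale alignment."""
    arrs, scales = zip(*terms)
    ref = np.max(scales, axis=0)
    total = np.zeros_like(arrs[0])
    for arr, sc in terms:
        with np.errstate(invalid="ignore"):
            weight = np.exp(sc - ref)
        total += arr * np.where(np.isfinite(weight), weight, 0.0)[:, None]
    return _scaled(total, ref)


def _tree_counts(d: SubsplitDAG):
    """Count analogues of the PLV recursions: subtree and rootward-context
    counts per node/clade/edge, and |T_e| per edge."""
    below: dict[Subsplit, int] = {}
    belowhat: dict[tuple[Subsplit, Which], int] = {}
    nodes_leafward = _leafward_order(d)
    for node in nodes_leafward:
        if node.is_leaf:
            below[node] = 1
            continue
        total = 1
        for which in (Which.LEFT, Which.RIGHT):
            if node.clade(which).is_empty:
                belowhat[(node, which)] = 1
                continue
            belowhat[(node, which)] = sum(
                below[k.child] for k in d.children(node, which)
            )
            total *= belowhat[(node, which)]
        below[node] = total

    rcount: dict[Subsplit, int] = {d.taxa.rho: 1}
    above: dict[EdgeKey, int] = {}
    for node in reversed(nodes_leafward):
        if node.is_leaf:
            continue
        assert node in rcount, f"rootward order violated at {node!r}"
        for which in (Which.LEFT, Which.RIGHT):
            for k in d.children(node, which):
                above[k] = rcount[node] * belowhat[(node, which.other)]
                rcount[k.child] = rcount.get(k.child, 0) + above[k]
    return below, belowhat, rcount, above


def count_trees_through_edge(d: SubsplitDAG, e: EdgeKey) -> int:
    """|T_e|: the number of trees of the sDAG containing edge e."""
    if not d.has_edge(e):
        raise SdagError(f"edge not in sDAG: {e!r}")
    below, _, _, above = _tree_counts(d)
    return above[e] * below[e.child]


@dataclass
class GPCaches:
    """Shared PLVs of a subsplit DAG: build once, query any edge.

    Invalidated by any change to the DAG's topology or branch lengths --
    callers rebuild rather than patch.
    """

    d: SubsplitDAG
    aln: Alignment
    p: dict = field(default_factory=dict)        # node -> (K,4), logscale (K,)
    phat: dict = field(default_factory=dict)     # (node, which) -> same
    r: dict = field(default_factory=dict)        # node -> same
    above: dict = field(default_factory=dict)    # edge -> same
    counts: tuple = ()

    def __post_init__(self) -> None:
        self.counts = _tree_counts(self.d)
        self._leafward()
        self._rootward()

    def _matrix(self, key: EdgeKey) -> np.ndarray:
        length = self.d.branch_length(key)
        if length is None:
            raise GPError(f"unset (sentinel) branch length on edge {key!r}")
        return jc_transition_matrix(length)

    def _leafward(self) -> None:
        d, aln = self.d, self.aln
        n_sites = aln.n_sites
        ones = np.ones((n_sites, 4)), np.zeros(n_sites)
        for node in _leafward_order(d):
            if node.is_leaf:
                self.p[node] = (
                    aln.leaf_partials(d.taxa.index(node.left.members[0])),
                    np.zeros(n_sites),
                )
                continue
            sides = []
            for which in (Which.LEFT, Which.RIGHT):
                if node.clade(which).is_empty:
                    self.phat[(node, which)] = ones
                else:
                    terms = []
                    for k in d.children(node, which):
                        child_arr, child_scale = self.p[k.child]
                        terms.append(
                            (child_arr @ self._matrix(k).T, child_scale)
                        )
                    self.phat[(node, which)] = _scaled_sum(terms)
                sides.append(self.phat[(node, which)])
            (la, ls), (ra, rs) = sides
            self.p[node] = _scaled(la * ra, ls + rs)

    def _rootward(self) -> None:
        d, aln = self.d, self.aln
        n_sites = aln.n_sites
        rho = d.taxa.rho
        pending: dict[Subsplit, list] = {}
        self.r[rho] = (np.full((n_sites, 4), 0.25), np.zeros(n_sites))
        for node in _rootward_order(d):
            if node.is_leaf:
                continue
            if node not in self.r:
                self.r[node] = _scaled_sum(pending[node])
            for which in (Which.LEFT, Which.RIGHT):
                if node.clade(which).is_empty:
                    continue
                r_arr, r_scale = self.r[node]
                sib_arr, sib_scale = self.phat[(node, which.other)]
                for k in d.children(node, which):
                    arr, scale = _scaled(
                        r_arr * sib_arr, r_scale + sib_scale
                    )
                    self.above[k] = (arr, scale)
                    if not k.child.is_leaf:
                        pending.setdefault(k.child, []).append(
                            (arr @ self._matrix(k), scale)
                        )

    # -- queries ------------------------------------------------------------

    def trees_through(self, e: EdgeKey) -> int:
        below, _, _, above = self.counts
        return above[e] * below[e.child]

    def edge_log_likelihood(self, e: EdgeKey) -> float:
        """The GP composite marginal log likelihood of edge e."""
        if not self.d.has_edge(e):
            raise SdagError(f"edge not in sDAG: {e!r}")
        above_arr, above_scale = self.above[e]
        p_arr, p_scale = self.p[e.child]
        site_sum = ((p_arr @ self._matrix(e).T) * above_arr).sum(axis=1)
        with np.errstate(divide="ignore"):
            site_ll = np.log(site_sum) + above_scale + p_scale
        n_trees = self.trees_through(e)
        return float(site_ll.sum()) - self.aln.n_sites * math.log(n_trees)


def gp_likelihood(
    d: SubsplitDAG,
    e: EdgeKey,
    aln: Alignment,
    caches: Optional[GPCaches] = None,
) -> float:
    """GP composite marginal log likelihood of edge e (shared-PLV DP)."""
    if caches is None:
        caches = GPCaches(d, aln)
    return caches.edge_log_likelihood(e)


# ---------------------------------------------------------------------------
# Brute-force oracles
# ---------------------------------------------------------------------------

def _trees_through_edge(d: SubsplitDAG, e: EdgeKey, cap: int):
    if not d.has_edge(e):
        raise SdagError(f"edge not in sDAG: {e!r}")
    n = count_trees_through_edge(d, e)
    if n > cap:
        raise GPError(f"|T_e| = {n} exceeds the enumeration cap {cap}")
    total = count_topologies(d)
    if total > max(cap * 1000, 100_000):
        raise GPError(f"sDAG has {total} topologies; enumeration refused")
    trees = [
        tree_from_sdag(d, topo)
        for topo in enumerate_topologies(d)
        if e in topo.edge_keys()
    ]
    assert len(trees) == n
    return trees


def gp_likelihood_bruteforce(
    d: SubsplitDAG, e: EdgeKey, aln: Alignment, cap: int = 5000
) -> float:
    """Eq-by-enumeration oracle for :func:`gp_likelihood`.

    Enumerates T_e, evaluates each tree's per-site likelihood with plain
    Felsenstein pruning, averages per site, and multiplies over sites.
    """
    trees = _trees_through_edge(d, e, cap)
    per_site = np.stack(
        [tree_log_likelihood(t, aln, per_site=True) for t in trees]
    )
    site_log_mean = logsumexp(per_site, axis=0) - math.log(len(trees))
    return float(site_log_mean.sum())


def true_marginal_bruteforce(
    d: SubsplitDAG, e: EdgeKey, aln: Alignment, cap: int = 5000
) -> float:
    """The exact (non-composite) marginal likelihood of an edge.

    Averages whole-alignment tree likelihoods over T_e.  Coincides with
    the GP composite at a single site or when |T_e| = 1; differs otherwise.
    No efficient shared-PLV computation is known; enumeration only.
    """
    trees = _trees_through_edge(d, e, cap)
    totals = np.array([tree_log_likelihood(t, aln) for t in trees])
    return float(logsumexp(totals) - math.log(len(trees)))


# ---------------------------------------------------------------------------
# Branch-length optimization under the GP objective
# ---------------------------------------------------------------------------

def gp_optimize_new_edges(
    d: SubsplitDAG,
    new_edges: Sequence[EdgeKey],
    aln: Alignment,
    config: Optional[SearchConfig] = None,
) -> dict[EdgeKey, float]:
    """Optimize each new edge's length against its own GP likelihood.

    Coordinate sweeps with a Brent line search per edge; lengths of old
    edges are never altered.  Mutates `d` in place and returns the final
    lengths of the new edges.
    """
    cfg = (config or SearchConfig()).optimizer
    edges = [k for k in sorted(new_edges) if not k.parent.is_rho]
    for _ in range(cfg.max_sweeps):
        max_change = 0.0
        for k in edges:
            current = d.branch_length(k)

            def objective(x: float, _k=k) -> float:
                d.set_branch_length(_k, x)
                return gp_likelihood(d, _k, aln)

            f_current = objective(current)
            x_new, f_new = brent_maximize(
                objective, cfg.min_branch_length, cfg.max_branch_length,
                cfg.xatol,
            )
            if f_new > f_current:
                d.set_branch_length(k, x_new)
                max_change = max(max_change, abs(x_new - current))
            else:
                d.set_branch_length(k, current)
        if max_change < cfg.tol:
            break
    return {k: d.branch_length(k) for k in edges}


# ---------------------------------------------------------------------------
# The GP search
# ---------------------------------------------------------------------------

@dataclass
class GPIteration:
    iteration: int
    central_edge: EdgeKey
    log_likelihood: float
    n_nodes: int
    n_edges: int
    n_topologies: int


@dataclass
class GPSearchResult:
    sdag: SubsplitDAG
    trace: list[GPIteration]


def _gp_score(
    d: SubsplitDAG,
    p: NNIProposal,
    aln: Alignment,
    config: SearchConfig,
) -> float:
    """GP likelihood of the central edge in the hypothetical post-NNI sDAG,
    with the new branch lengths optimized (overlay discarded afterwards)."""
    overlay, new_edges, counterparts = apply_nni_detailed(
        d, p, completion="around_new_nodes"
    )
    for k in new_edges:
        src = counterparts.get(k)
        length = d.branch_length(src) if src is not None else None
        overlay.set_branch_length(
            k, length if length is not None else config.default_branch_length
        )
    gp_optimize_new_edges(overlay, new_edges, aln, config)
    return gp_likelihood(overlay, p.central, aln)


def gp_search(
    trees: Sequence[Tree],
    aln: Alignment,
    stop,
    config: Optional[SearchConfig] = None,
    init_global_opt: str | bool = False,
) -> GPSearchResult:
    """The generalized-pruning systematic search.

    Initializes the DAG spanned by the input trees (branch lengths from the
    first tree containing each edge, optionally refined against the GP
    objective), completes all compatible edges with GP-optimized lengths,
    then repeatedly applies the highest-GP-likelihood enlarging NNI with
    around-new-nodes completion.  Queue scores are computed once and never
    refreshed.  `init_global_opt` may be False, "per_edge" (refine every
    starting edge against its own GP likelihood) or "whole" (refine against
    the GP likelihood at the rho edge, i.e. the whole-DAG composite).
    """
    from .top_pruning import StopRule  # shared stop-rule type

    cfg = config or SearchConfig()
    if not trees:
        raise GPError("at least one input tree is required")
    dag, _ = sdag_from_trees(trees)

    if init_global_opt:
        all_edges = [k for k in dag.edges() if not k.parent.is_rho]
        if init_global_opt == "whole":
            rho_edges = [k for k in dag.edges() if k.parent.is_rho]
            opt = cfg.optimizer
            for _ in range(opt.max_sweeps):
                max_change = 0.0
                for k in all_edges:
                    current = dag.branch_length(k)

                    def whole(x: float, _k=k) -> float:
                        dag.set_branch_length(_k, x)
                        caches = GPCaches(dag, aln)
                        return sum(
                            caches.edge_log_likelihood(r) for r in rho_edges
                        )

                    f_cur = whole(current)
                    x_new, f_new = brent_maximize(
                        whole, opt.min_branch_length, opt.max_branch_length,
                        opt.xatol,
                    )
                    if f_new > f_cur:
                        dag.set_branch_length(k, x_new)
                        max_change = max(max_change, abs(x_new - current))
                    else:
                        dag.set_branch_length(k, current)
                if max_change < opt.tol:
                    break
        else:
            gp_optimize_new_edges(dag, all_edges, aln, cfg)

    before = dag.edge_keys()
    complete_edges(dag, in_place=True)
    completion_new = sorted(dag.edge_keys() - before)
    for k in completion_new:
        dag.set_branch_length(k, cfg.default_branch_length)
    gp_optimize_new_edges(dag, completion_new, aln, cfg)

    queue: list = []
    seen: set[EdgeKey] = set()

    def insert(p: NNIProposal) -> None:
        queue.append((_gp_score(dag, p, aln, cfg), p))
        queue.sort(key=lambda e: (-e[0], e[1].central))

    for p in candidate_nnis(dag):
        seen.add(p.central)
        insert(p)

    trace: list[GPIteration] = []
    iteration = 0
    while iteration < stop.max_iterations:
        while queue and not proposal_is_enlarging(dag, queue[0][1]):
            queue.pop(0)
        if not queue or queue[0][0] < stop.likelihood_threshold:
            break
        score, p = queue.pop(0)
        iteration += 1

        new_dag, new_edges, counterparts = apply_nni_detailed(
            dag, p, completion="around_new_nodes"
        )
        for k in new_edges:
            src = counterparts.get(k)
            length = dag.branch_length(src) if src is not None else None
            new_dag.set_branch_length(
                k, length if length is not None else cfg.default_branch_length
            )
        dag = new_dag
        gp_optimize_new_edges(dag, new_edges, aln, cfg)

        trace.append(GPIteration(
            iteration, p.central, score,
            dag.n_nodes, dag.n_edges, count_topologies(dag),
        ))

        for q in candidate_nnis(dag):
            if q.central in seen:
                continue
            seen.add(q.central)
            insert(q)
    return GPSearchResult(dag, trace)
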