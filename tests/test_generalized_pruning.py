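import math

import numpy as np
import pytest

from sdagsearch import (
    EdgeKey,
    GPCaches,
    SearchConfig,
    StopRule,
    Which,
    complete_edges,
    contains_topology,
    count_topologies,
    count_trees_through_edge,
    enumerate_topologies,
    gp_likelihood,
    gp_likelihood_bruteforce,
    gp_optimize_new_edges,
    gp_search,
    make_subsplit,
    sdag_from_topologies,
    sdag_from_trees,
    tree_log_likelihood,
    true_marginal_bruteforce,
)
from sdagsearch.generalized_pruning import GPError
from sdagsearch.simulate import (
    default_taxa,
    random_tree,
    simulate_jc_alignment,
)
from sdagsearch.subsplits import make_clade

from conftest import tree_with_random_lengths


def randomized_sdag(rng, n_taxa=None, n_trees=None):
    n = n_taxa or int(rng.integers(3, 7))
    k = n_trees or int(rng.integers(1, 5))
    trees = [random_tree(n, rng) for _ in range(k)]
    d, _ = sdag_from_trees(trees)
    for key in d.edges():
        if not key.parent.is_rho:
            d.set_branch_length(key, float(rng.exponential(0.1)))
    return d, trees


@pytest.fixture(scope="module")
def fig1_with_lengths(fig1_sdag):
    d = fig1_sdag.copy()
    rng = np.random.default_rng(303)
    for key in d.edges():
        if not key.parent.is_rho:
            d.set_branch_length(key, float(rng.exponential(0.1)))
    return d


class TestTreeCounts:
    def test_single_topology_every_edge_counts_one(self):
        rng = np.random.default_rng(1)
        d, _ = randomized_sdag(rng, n_trees=1)
        assert all(count_trees_through_edge(d, e) == 1 for e in d.edges())

    def test_fig1_central_edge_counts_two(self, fig1_with_lengths, taxa7):
        edge = EdgeKey(
            make_subsplit(
                make_clade(["3"], taxa7), make_clade(["4", "5", "6"], taxa7)
            ),
            Which.RIGHT,
            make_subsplit(make_clade(["4"], taxa7), make_clade(["5", "6"], taxa7)),
        )
        assert count_trees_through_edge(fig1_with_lengths, edge) == 2

    def test_counts_match_enumeration_exactly(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            d, _ = randomized_sdag(rng)
            topologies = enumerate_topologies(d)
            for e in d.edges():
                expected = sum(1 for t in topologies if e in t.edge_keys())
                assert count_trees_through_edge(d, e) == expected

    def test_partition_identity_over_sibling_edges(self):
        """Summing |T_e| over the outgoing edges of a (node, clade) gives
        the number of trees through that choice point."""
        rng = np.random.default_rng(3)
        d, _ = randomized_sdag(rng, n_taxa=6, n_trees=3)
        topologies = enumerate_topologies(d)
        for node in d.nodes:
            for which in (Which.LEFT, Which.RIGHT):
                kids = d.children(node, which)
                if len(kids) < 2:
                    continue
                total = sum(count_trees_through_edge(d, e) for e in kids)
                through_point = sum(
                    1
                    for t in topologies
                    if any(e in t.edge_keys() for e in kids)
                )
                assert total == through_point


class TestGPLikelihood:
    def test_single_topology_equals_tree_likelihood_everywhere(self):
        rng = np.random.default_rng(4)
        d, trees = randomized_sdag(rng, n_taxa=5, n_trees=1)
        aln = simulate_jc_alignment(trees[0], 5, rng)
        caches = GPCaches(d, aln)
        reference = None
        for e in d.edges():
            value = caches.edge_log_likelihood(e)
            if reference is None:
                reference = value
            assert value == pytest.approx(reference, abs=1e-9)
        topo = enumerate_topologies(d)[0]
        from sdagsearch.sdag import tree_from_sdag

        assert reference == pytest.approx(
            tree_log_likelihood(tree_from_sdag(d, topo), aln), abs=1e-9
        )

    def test_two_trees_one_site_is_log_mean(self, fig1_with_lengths, taxa7):
        rng = np.random.default_rng(5)
        aln = simulate_jc_alignment(random_tree(taxa7, rng), 1, rng)
        edge = EdgeKey(
            make_subsplit(
                make_clade(["3"], taxa7), make_clade(["4", "5", "6"], taxa7)
            ),
            Which.RIGHT,
            make_subsplit(make_clade(["4"], taxa7), make_clade(["5", "6"], taxa7)),
        )
        d = fig1_with_lengths
        from sdagsearch.sdag import tree_from_sdag

        lls = [
            tree_log_likelihood(tree_from_sdag(d, t), aln)
            for t in enumerate_topologies(d)
            if edge in t.edge_keys()
        ]
        assert len(lls) == 2
        expected = math.log((math.exp(lls[0]) + math.exp(lls[1])) / 2)
        assert gp_likelihood(d, edge, aln) == pytest.approx(expected, abs=1e-10)

    def test_dp_matches_bruteforce_on_randomized_instances(self):
        rng = np.random.default_rng(6)
        for _ in range(40):
            d, trees = randomized_sdag(rng)
            aln = simulate_jc_alignment(trees[0], int(rng.integers(1, 4)), rng)
            caches = GPCaches(d, aln)
            edges = d.edges()
            for e in [edges[int(rng.integers(len(edges)))] for _ in range(2)]:
                assert caches.edge_log_likelihood(e) == pytest.approx(
                    gp_likelihood_bruteforce(d, e, aln), abs=1e-9
                )

    def test_bounded_by_extreme_single_tree_likelihoods(self):
        """Per-site averaging keeps GP between the min and max per-edge
        single-tree log likelihoods."""
        rng = np.random.default_rng(7)
        d, trees = randomized_sdag(rng, n_taxa=5, n_trees=2)
        aln = simulate_jc_alignment(trees[0], 4, rng)
        from sdagsearch.sdag import tree_from_sdag

        for e in d.edges():
            members = [
                t for t in enumerate_topologies(d) if e in t.edge_keys()
            ]
            per_site = np.stack([
                tree_log_likelihood(tree_from_sdag(d, t), aln, per_site=True)
                for t in members
            ])
            lower = float(per_site.min(axis=0).sum())
            upper = float(per_site.max(axis=0).sum())
            value = gp_likelihood(d, e, aln)
            assert lower - 1e-9 <= value <= upper + 1e-9

    def test_sentinel_length_raises(self, fig1_sdag):
        rng = np.random.default_rng(8)
        aln = simulate_jc_alignment(random_tree(7, rng), 2, rng)
        edge = fig1_sdag.edges()[3]
        with pytest.raises(GPError, match="sentinel"):
            gp_likelihood(fig1_sdag, edge, aln)


class TestTrueMarginal:
    def test_single_tree_and_single_site_coincide_with_gp(self, fig1_with_lengths, taxa7):
        rng = np.random.default_rng(9)
        aln1 = simulate_jc_alignment(random_tree(taxa7, rng), 1, rng)
        d = fig1_with_lengths
        for e in d.edges()[:4]:
            assert true_marginal_bruteforce(d, e, aln1) == pytest.approx(
                gp_likelihood(d, e, aln1), abs=1e-9
            )

    def test_composite_differs_from_true_marginal_at_multiple_sites(
        self, fig1_with_lengths, taxa7
    ):
        rng = np.random.default_rng(10)
        aln = simulate_jc_alignment(random_tree(taxa7, rng), 6, rng)
        d = fig1_with_lengths
        edge = next(
            e for e in d.edges() if count_trees_through_edge(d, e) > 1
        )
        gp = gp_likelihood(d, edge, aln)
        marginal = true_marginal_bruteforce(d, edge, aln)
        assert abs(gp - marginal) > 1e-6


class TestGPOptimize:
    def test_single_topology_matches_single_tree_ml(self):
        """With |T_e| = 1 the GP objective degenerates to the tree
        likelihood, so GP optimization of one sentinel edge equals plain
        single-tree branch optimization."""
        rng = np.random.default_rng(11)
        d, trees = randomized_sdag(rng, n_taxa=4, n_trees=1)
        aln = simulate_jc_alignment(trees[0], 200, rng)
        target = next(e for e in d.edges() if not e.parent.is_rho)
        original = d.branch_length(target)
        d.set_branch_length(target, 0.5)
        gp_optimize_new_edges(d, [target], aln)
        from sdagsearch.phylo import brent_maximize
        from sdagsearch.sdag import tree_from_sdag

        topo = enumerate_topologies(d)[0]
        base = tree_from_sdag(d, topo)

        def direct(x):
            from sdagsearch import Tree

            trial = dict(base.lengths)
            trial[target] = x
            return tree_log_likelihood(Tree(topo, trial), aln)

        expected, _ = brent_maximize(direct, 1e-6, 10.0, 1e-5)
        assert d.branch_length(target) == pytest.approx(expected, abs=1e-3)

    def test_brent_matches_grid_search(self):
        from sdagsearch import parse_newick_topology

        taxa = default_taxa(5)
        rng = np.random.default_rng(12)
        t1 = tree_with_random_lengths(
            parse_newick_topology("(0,(1,(2,(3,4))));", taxa), rng
        )
        t2 = tree_with_random_lengths(
            parse_newick_topology("(1,(0,((2,3),4)));", taxa), rng
        )
        d, _ = sdag_from_trees([t1, t2])
        complete_edges(d, in_place=True)
        for e in d.edges():
            if d.branch_length(e) is None:
                d.set_branch_length(e, 0.1)
        aln = simulate_jc_alignment(t1, 50, rng)
        target = next(
            e for e in d.edges()
            if not e.parent.is_rho and count_trees_through_edge(d, e) > 1
        )
        gp_optimize_new_edges(d, [target], aln)
        optimized = d.branch_length(target)
        grid = np.arange(1e-6, 1.0, 1e-3)
        values = []
        for x in grid:
            d.set_branch_length(target, float(x))
            values.append(gp_likelihood(d, target, aln))
        best_grid = float(grid[int(np.argmax(values))])
        d.set_branch_length(target, optimized)
        assert abs(optimized - best_grid) < 2e-3


class TestGPSearch:
    def test_infinite_threshold_returns_completed_initial_sdag(self):
        rng = np.random.default_rng(13)
        tree = random_tree(4, rng)
        aln = simulate_jc_alignment(tree, 60, rng)
        result = gp_search(
            [tree], aln,
            StopRule(max_iterations=20, likelihood_threshold=math.inf),
        )
        assert result.trace == []
        expected, _ = complete_edges(sdag_from_topologies([tree.topology]))
        assert result.sdag.edge_keys() == expected.edge_keys()

    def test_deterministic_and_monotone(self):
        rng = np.random.default_rng(14)
        tree = random_tree(4, np.random.default_rng(14))
        aln = simulate_jc_alignment(tree, 60, rng)
        first = gp_search([tree], aln, StopRule(max_iterations=4))
        second = gp_search([tree], aln, StopRule(max_iterations=4))
        assert [
            (it.central_edge, it.log_likelihood) for it in first.trace
        ] == [(it.central_edge, it.log_likelihood) for it in second.trace]
        counts = [it.n_topologies for it in first.trace]
        assert counts == sorted(counts)
        assert contains_topology(first.sdag, tree.topology)
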