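import itertools
import math

import numpy as np
import pytest

from sdagsearch import (
    EdgeKey,
    SearchConfig,
    StopRule,
    Tree,
    Which,
    apply_nni,
    best_known_tree,
    candidate_nnis,
    complete_edges,
    contains_topology,
    count_topologies,
    enumerate_topologies,
    extend_argmax,
    init_from_tree_list,
    make_subsplit,
    parse_newick_topology,
    proposals_for_edge,
    sdag_from_topologies,
    tp_likelihood,
    tp_search,
    tree_log_likelihood,
)
from sdagsearch.nni import apply_nni_detailed
from sdagsearch.phylo import brent_maximize
from sdagsearch.sdag import tree_from_sdag
from sdagsearch.simulate import (
    default_taxa,
    exhaustive_ml_tree,
    random_tree,
    simulate_jc_alignment,
)
from sdagsearch.subsplits import make_clade
from sdagsearch.top_pruning import TopPruningError

from conftest import tree_with_random_lengths


@pytest.fixture(scope="module")
def single_tree_state():
    rng = np.random.default_rng(77)
    tree = random_tree(5, rng)
    aln = simulate_jc_alignment(tree, 150, rng)
    return init_from_tree_list([tree], aln), tree, aln


@pytest.fixture(scope="module")
def fig5_state(fig5_trees):
    tau0, tau1, aln = fig5_trees
    return init_from_tree_list([tau0, tau1], aln)


class TestInit:
    def test_edges_labeled_by_first_containing_tree(self, fig5_trees):
        tau0, tau1, aln = fig5_trees
        state = init_from_tree_list([tau0, tau1], aln)
        keys0 = tau0.topology.edge_keys()
        keys1 = tau1.topology.edge_keys()
        for key in keys0:
            assert state.edge_first_tree[key] == 0
            assert state.sdag.branch_length(key) == tau0.lengths[key]
        for key in keys1 - keys0:
            assert state.edge_first_tree[key] == 1
            assert state.sdag.branch_length(key) == tau1.lengths[key]

    def test_empty_tree_list_rejected(self, fig5_trees):
        with pytest.raises(TopPruningError, match="at least one"):
            init_from_tree_list([], fig5_trees[2])

    def test_unordered_list_rejected_when_verifying(self, fig5_trees):
        tau0, tau1, aln = fig5_trees
        config = SearchConfig(verify_tree_order=True)
        init_from_tree_list([tau0, tau1], aln, config)  # correct order passes
        with pytest.raises(TopPruningError, match="ordered"):
            init_from_tree_list([tau1, tau0], aln, config)

    def test_fig5_sibling_question_resolves_to_first_tree(self, fig5_state, taxa7):
        """'Does {{2},{3,4,5}} -> {2} use the sibling edge to {{3},{4,5}} or
        {{3,4},{5}}?' -- the edge appears first in tau0, whose resolution is
        {{3},{4,5}}."""
        parent = make_subsplit(
            make_clade(["2"], taxa7), make_clade(["3", "4", "5"], taxa7)
        )
        edge = EdgeKey(parent, Which.LEFT, taxa7.leaf_subsplit("2"))
        sibling = fig5_state.choice[edge].sibling
        assert sibling.child == make_subsplit(
            make_clade(["3"], taxa7), make_clade(["4", "5"], taxa7)
        )


class TestBestKnownTree:
    def test_single_tree_sdag_returns_it_from_every_edge(self, single_tree_state):
        state, tree, _ = single_tree_state
        for edge in state.sdag.edges():
            assert best_known_tree(state, edge).topology == tree.topology

    def test_fig5_tau0_edges_return_tau0(self, fig5_state, fig5_trees):
        tau0 = fig5_trees[0]
        for edge, label in fig5_state.edge_first_tree.items():
            if label == 0:
                bkt = best_known_tree(fig5_state, edge)
                assert bkt.topology == tau0.topology

    def test_fig5_tau1_edges_split_into_tau2_and_tau3(
        self, fig5_state, fig5_trees, taxa7
    ):
        """Edges first appearing in tau1 yield the two mixed topologies,
        split exactly at the shared subsplit {{1},{2,3,4,5}}: tau1's
        rootward structure + tau0's resolution of {3,4,5} above, and the
        reverse mixture below."""
        tau2 = parse_newick_topology("((0,(1,(2,(3,(4,5))))),6);", taxa7)
        tau3 = parse_newick_topology("(0,((1,(2,((3,4),5))),6));", taxa7)
        pivot = make_subsplit(
            make_clade(["1"], taxa7), make_clade(["2", "3", "4", "5"], taxa7)
        )
        below_clade = pivot.union.mask
        for edge, label in fig5_state.edge_first_tree.items():
            if label != 1:
                continue
            bkt = best_known_tree(fig5_state, edge).topology
            is_below = (
                edge.parent.union.mask | below_clade == below_clade
            )
            assert bkt == (tau3 if is_below else tau2), edge

    def test_output_contained_in_sdag_and_contains_edge(self, fig5_state):
        for edge in fig5_state.sdag.edges():
            bkt = best_known_tree(fig5_state, edge)
            assert contains_topology(fig5_state.sdag, bkt.topology)
            assert edge in bkt.topology.edge_keys()


class TestExtendArgmax:
    def test_no_new_edges_is_a_no_op(self, fig5_state):
        before = {k: vars(v).copy() for k, v in fig5_state.choice.items()}
        extend_argmax(fig5_state, [])
        after = {k: vars(v).copy() for k, v in fig5_state.choice.items()}
        assert before == after

    def test_forced_slots_take_single_candidate(self, single_tree_state):
        state, tree, _ = single_tree_state
        for edge, entry in state.choice.items():
            if entry.left is not None:
                candidates = state.sdag.children(edge.child, Which.LEFT)
                if len(candidates) == 1:
                    assert entry.left == candidates[0]

    def test_argmax_choices_beat_alternatives(self):
        """On the 5-taxon completion example, each completion edge's chosen
        best known tree has maximal likelihood over all slot-candidate
        combinations (exhaustive check)."""
        taxa = default_taxa(5)
        rng = np.random.default_rng(55)
        t1 = tree_with_random_lengths(
            parse_newick_topology("(0,(1,(2,(3,4))));", taxa), rng
        )
        t2 = tree_with_random_lengths(
            parse_newick_topology("(1,(0,((2,3),4)));", taxa), rng
        )
        aln = simulate_jc_alignment(t1, 120, rng)
        trees = sorted(
            [t1, t2], key=lambda t: -tree_log_likelihood(t, aln)
        )
        state = init_from_tree_list(trees, aln)
        completion_edges = [
            k for k in state.sdag.edges() if k not in state.edge_first_tree
        ]
        assert completion_edges
        from sdagsearch.top_pruning import _slot_candidates

        for edge in completion_edges:
            chosen_ll = tree_log_likelihood(
                best_known_tree(state, edge), aln
            )
            rootward, left, right = _slot_candidates(state, edge)
            entry = state.choice[edge]
            saved = vars(entry).copy()
            best = -math.inf
            for combo_root in rootward or [None]:
                for combo_left in left or [None]:
                    for combo_right in right or [None]:
                        if combo_root is not None:
                            entry.parent, entry.sibling = combo_root
                        if combo_left is not None:
                            entry.left = combo_left
                        if combo_right is not None:
                            entry.right = combo_right
                        value = tree_log_likelihood(
                            best_known_tree(state, edge), aln
                        )
                        best = max(best, value)
            for field, value in saved.items():
                setattr(entry, field, value)
            assert chosen_ll == pytest.approx(best, abs=1e-9)


class TestTPLikelihood:
    def test_cherry_proposals_match_direct_tree_likelihood(self):
        """Both NNIs of the 4-taxon cherry edge score exactly the
        Felsenstein likelihood of the alternative topology, with inherited
        lengths and the central branch optimized."""
        taxa = default_taxa(4)
        rng = np.random.default_rng(21)
        tree = tree_with_random_lengths(
            parse_newick_topology("((0,1),(2,3));", taxa), rng
        )
        aln = simulate_jc_alignment(tree, 100, rng)
        state = init_from_tree_list([tree], aln)
        cherry = EdgeKey(
            make_subsplit(make_clade(["0", "1"], taxa), make_clade(["2", "3"], taxa)),
            Which.LEFT,
            make_subsplit(make_clade(["0"], taxa), make_clade(["1"], taxa)),
        )
        for p in proposals_for_edge(cherry):
            score = tp_likelihood(state, p)
            _, _, counterparts = apply_nni_detailed(
                state.sdag, p, "around_new_nodes"
            )
            alternative = next(
                t
                for t in enumerate_topologies(apply_nni(state.sdag, p, "none"))
                if t != tree.topology
            )
            lengths = {}
            for k in alternative.edge_keys():
                if state.sdag.has_edge(k):
                    lengths[k] = state.sdag.branch_length(k)
                else:
                    lengths[k] = state.sdag.branch_length(counterparts[k])

            def direct(x):
                trial = dict(lengths)
                trial[p.central] = x
                return tree_log_likelihood(Tree(alternative, trial), aln)

            _, expected = brent_maximize(direct, 1e-6, 10.0, 1e-5)
            assert score == pytest.approx(expected, abs=1e-8)

    def test_bounded_by_max_likelihood_over_trees_through_edge(self):
        """The top-pruning score never exceeds the true maximum of the
        classical likelihood over T_e with the central branch optimized
        (enumeration oracle for the ideal selection criterion)."""
        taxa = default_taxa(5)
        rng = np.random.default_rng(31)
        trees = [random_tree(taxa, rng) for _ in range(2)]
        aln = simulate_jc_alignment(trees[0], 3, rng)
        trees = sorted(trees, key=lambda t: -tree_log_likelihood(t, aln))
        state = init_from_tree_list(trees, aln)
        for p in candidate_nnis(state.sdag)[:6]:
            score = tp_likelihood(state, p)
            overlay, _, counterparts = apply_nni_detailed(
                state.sdag, p, "around_new_nodes"
            )
            for k in overlay.edges():
                if overlay.branch_length(k) is None:
                    src = counterparts.get(k)
                    overlay.set_branch_length(
                        k,
                        state.sdag.branch_length(src) if src else 0.1,
                    )
            best = -math.inf
            for topo in enumerate_topologies(overlay):
                if p.central not in topo.edge_keys():
                    continue
                base = tree_from_sdag(overlay, topo)

                def with_central(x, _b=base):
                    trial = dict(_b.lengths)
                    trial[p.central] = x
                    return tree_log_likelihood(Tree(_b.topology, trial), aln)

                best = max(best, brent_maximize(with_central, 1e-6, 10.0, 1e-5)[1])
            assert score <= best + 1e-6


class TestTPSearch:
    def test_infinite_threshold_returns_initial_sdag(self, fig5_trees):
        tau0, tau1, aln = fig5_trees
        result = tp_search(
            [tau0, tau1], aln, StopRule(max_iterations=50,
                                        likelihood_threshold=math.inf)
        )
        assert result.trace == []
        expected, _ = complete_edges(
            sdag_from_topologies([tau0.topology, tau1.topology])
        )
        assert result.sdag.edge_keys() == expected.edge_keys()

    def test_popped_scores_are_queue_maxima_and_growth_is_monotone(self):
        rng = np.random.default_rng(61)
        tree = random_tree(4, rng)
        aln = simulate_jc_alignment(tree, 200, rng)
        result = tp_search([tree], aln, StopRule(max_iterations=8))
        counts = [it.n_topologies for it in result.trace]
        edges = [it.n_edges for it in result.trace]
        assert counts == sorted(counts)
        assert edges == sorted(edges)

    def test_recovers_generating_topology_from_ml_start(self):
        rng = np.random.default_rng(71)
        generating = random_tree(4, rng)
        aln = simulate_jc_alignment(generating, 500, rng)
        start = exhaustive_ml_tree(aln)
        result = tp_search([start], aln, StopRule(max_iterations=30))
        assert contains_topology(result.sdag, generating.topology)
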