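import numpy as np
import pytest

from sdagsearch import (
    Tree,
    parse_newick_topology,
    sdag_from_topologies,
)
from sdagsearch.simulate import (
    default_taxa,
    simulate_jc_alignment,
)


@pytest.fixture(scope="session")
def taxa7():
    return default_taxa(7)


@pytest.fixture(scope="session")
def fig1_topologies(taxa7):
    """The caterpillar and the second 7-taxon topology whose union is the
    worked-example sDAG with two root splits and two resolutions of
    {4, 5, 6}."""
    t1 = parse_newick_topology("(0,(1,(2,(3,(4,(5,6))))));", taxa7)
    t2 = parse_newick_topology("((0,1),(2,(3,((4,6),5))));", taxa7)
    return t1, t2


@pytest.fixture(scope="session")
def fig1_sdag(fig1_topologies):
    return sdag_from_topologies(list(fig1_topologies))


@pytest.fixture(scope="session")
def fig5_topologies(taxa7):
    """Two 7-taxon trees whose union sDAG contains exactly two extra
    (mixed) topologies; the basis of the choice-map worked example."""
    tau0 = parse_newick_topology("(0,((1,(2,(3,(4,5)))),6));", taxa7)
    tau1 = parse_newick_topology("((0,(1,(2,((3,4),5)))),6);", taxa7)
    return tau0, tau1


def tree_with_random_lengths(topo, rng, mean=0.1):
    return Tree(
        topo,
        {
            k: (0.0 if k.parent.is_rho else float(rng.exponential(mean)))
            for k in sorted(topo.edge_keys())
        },
    )


@pytest.fixture(scope="session")
def fig5_trees(fig5_topologies):
    """The two topologies with branch lengths, plus an alignment simulated
    on tau0 so that tau0 genuinely has the higher likelihood."""
    tau0_topo, tau1_topo = fig5_topologies
    rng = np.random.default_rng(20240)
    tau0 = tree_with_random_lengths(tau0_topo, rng)
    tau1 = tree_with_random_lengths(tau1_topo, rng)
    aln = simulate_jc_alignment(tau0, 300, rng)
    return tau0, tau1, aln
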