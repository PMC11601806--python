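"""Build a subsplit DAG from two rooted topologies and put a probability
distribution on it.

The union of two 7-taxon topologies already contains more topologies than
its inputs: the DAG has two root-split options and two resolutions of the
clade {4,5,6}, so 2 x 2 = 4 topologies.  Assigning probabilities to the
edges leaving each choice point turns the DAG into a distribution over
those topologies; a topology's probability is the product of its edges'
conditional probabilities.
"""

from sdagsearch import (
    EdgeProbabilities,
    Which,
    count_topologies,
    enumerate_topologies,
    make_clade,
    make_subsplit,
    parse_newick_topology,
    sdag_from_topologies,
    topology_probability,
)
from sdagsearch.simulate import default_taxa

taxa = default_taxa(7)
t1 = parse_newick_topology("(0,(1,(2,(3,(4,(5,6))))));", taxa)
t2 = parse_newick_topology("((0,1),(2,(3,((4,6),5))));", taxa)
dag = sdag_from_topologies([t1, t2])

print(f"nodes: {dag.n_nodes}, edges: {dag.n_edges}")
print(f"topologies in the DAG: {count_topologies(dag)}  (built from 2)")
for topo in enumerate_topologies(dag):
    print("  ", topo.newick())

# probability 0.4 for the {{0,1},{2..6}} root split, 0.3 for {{4},{5,6}}
table = dict(EdgeProbabilities.uniform(dag).table)
rs1 = make_subsplit(make_clade(["0", "1"], taxa),
                    make_clade(["2", "3", "4", "5", "6"], taxa))
rs2 = make_subsplit(make_clade(["0"], taxa),
                    make_clade(["1", "2", "3", "4", "5", "6"], taxa))
t345 = make_subsplit(make_clade(["3"], taxa), make_clade(["4", "5", "6"], taxa))
c1 = make_subsplit(make_clade(["4"], taxa), make_clade(["5", "6"], taxa))
c2 = make_subsplit(make_clade(["4", "6"], taxa), make_clade(["5"], taxa))
table[(taxa.rho, Which.RIGHT)] = {rs1: 0.4, rs2: 0.6}
table[(t345, Which.RIGHT)] = {c1: 0.3, c2: 0.7}
probs = EdgeProbabilities(dag, table)

target = parse_newick_topology("((0,1),(2,(3,(4,(5,6)))));", taxa)
p = topology_probability(dag, probs, target)
print(f"P(((0,1),(2,(3,(4,(5,6)))))) = {p}   # 0.4 x 0.3")
total = sum(topology_probability(dag, probs, t)
            for t in enumerate_topologies(dag))
print(f"sum over all {count_topologies(dag)} topologies = {total}")
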