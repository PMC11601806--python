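"""Run the top-pruning NNI search on a simulated data set.

A random 5-taxon tree generates a 500-site Jukes-Cantor alignment; the
search starts from the exhaustive maximum-likelihood tree and repeatedly
applies the NNI whose best-known-tree likelihood is highest, growing the
subsplit DAG.  The trace shows the score of each applied NNI (the log
likelihood of the best known tree through its central edge) and how the
DAG, and the number of topologies it represents, grows per iteration.
"""

import numpy as np

from sdagsearch import StopRule, contains_topology, tp_search
from sdagsearch.simulate import (
    exhaustive_ml_tree,
    random_tree,
    simulate_jc_alignment,
)

rng = np.random.default_rng(515)
generating = random_tree(5, rng)
aln = simulate_jc_alignment(generating, 500, rng)
print("generating topology:", generating.topology.newick())

start = exhaustive_ml_tree(aln)
print("ML starting topology:", start.topology.newick())

result = tp_search([start], aln, StopRule(max_iterations=15))
print("iter  tp-log-lik   nodes  edges  topologies")
for it in result.trace:
    print(f"{it.iteration:4d}  {it.log_likelihood:10.2f}   "
          f"{it.n_nodes:5d}  {it.n_edges:5d}  {it.n_topologies:10d}")

found = contains_topology(result.sdag, generating.topology)
print("final sDAG contains the generating topology:", found)
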