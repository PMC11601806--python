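"""Evaluate a subsplit DAG against an empirical posterior.

The empirical posterior is a topology -> density table (in practice, from
a long MCMC run).  We build a DAG from the two highest-density topologies
and measure: how much posterior density its topologies capture, the size
of the 95% credible set, and the credibility of its subsplits (a subsplit
is credible if some credible-set topology contains it).
"""

import numpy as np

from sdagsearch import (
    PosteriorTable,
    coverage,
    credible_set,
    sdag_from_topologies,
    subsplit_credibility,
)
from sdagsearch.simulate import all_rooted_topologies, default_taxa

taxa = default_taxa(5)
rng = np.random.default_rng(3)
topologies = all_rooted_topologies(taxa)
weights = rng.dirichlet(np.full(len(topologies), 0.05))
order = np.argsort(-weights)
post = PosteriorTable({
    topologies[i]: float(weights[i]) for i in order[:20]
})
print(f"posterior over {len(post)} topologies, "
      f"total density {post.total_density:.3f}")

credible = credible_set(post, 0.95)
print(f"95% credible set size: {len(credible)}")

best_two = sorted(post.densities, key=post.densities.get, reverse=True)[:2]
dag = sdag_from_topologies(best_two)
print("sDAG spanned by the top-2 topologies:")
print(f"  coverage (posterior density in the DAG): {coverage(dag, post):.4f}")
found, precision = subsplit_credibility(dag, credible)
print(f"  credible subsplits found: {found:.3f}")
print(f"  DAG subsplits that are credible: {precision:.3f}")
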