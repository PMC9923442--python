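"""Quintet topology probabilities under the coalescent, and rooting costs.

A rooted 5-taxon species tree induces a probability distribution over the
15 unrooted gene-tree topologies under the multispecies coalescent. The
*shape* of that distribution (which probabilities are equal, which exceed
which) depends on where the root is -- that is what makes rooting from
unrooted gene trees possible. The rooting cost is zero exactly when a
distribution satisfies all equalities and orderings of a rooted topology.
"""

import numpy as np

from multiroot import QuintetCatalog, msc_quintet_probs, parse_newick, rooting_cost
from multiroot.quintet import QuintetDistribution

species_tree = parse_newick("((((a,b),c),d),e);")
for v in species_tree.postorder():
    if not v.is_leaf and v is not species_tree.root:
        v.length = 0.5  # coalescent units: moderate ILS

probs = msc_quintet_probs(species_tree, n_samples=500_000, seed=1)
cat = QuintetCatalog(list("abcde"))
print("top topology probabilities:")
for idx in np.argsort(probs)[::-1][:4]:
    print(f"  {cat.unrooted_newicks[idx]:28s} {probs[idx]:.3f}")

dist = QuintetDistribution(probs, support=500_000)
rid_true = cat.rooted_id(species_tree)
topo = cat.matching_index(rid_true)
print("\ncost of each rooting of the matching unrooted topology:")
for rid in cat.rootings[topo]:
    cost = rooting_cost(cat.structure_of(rid), dist)
    marker = "  <-- true rooting" if rid == rid_true else ""
    print(f"  {cat.shape_of(rid):20s} cost {cost:.4f}{marker}")
print("\nThe true rooting costs ~0; rootings far from the truth pay a large penalty.")
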