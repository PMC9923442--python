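"""Decompose multi-copy gene family trees into single-copy trees.

Gene family trees carry several copies per species when genes duplicate.
The decomposition roots each tree so as to minimize the implied number of
duplications, tags every internal node as duplication or speciation, and
cuts the tree at duplication nodes so each output contains at most one
copy per species (orthologs only, if the rooting was correct).
"""

from multiroot import SpeciesMapping, parse_newick
from multiroot.disco import decompose, disco, optimal_root

mapping = SpeciesMapping.delimiter("_")  # "HUMAN_2" -> species "HUMAN"

# one ancient duplication: copies 1 and 2 of each species form two clean
# ortholog groups
family = parse_newick("(((A_1,(B_1,C_1)),((A_2,B_2),C_2)),D_1);", rooted_hint=False)

tagged = optimal_root(family, mapping)
print(f"optimal rooting implies {tagged.dup_count} duplication(s)")

result = decompose(tagged, min_size=2)
for t in result.trees:
    print("  single-copy tree:", t.newick())

# the batch interface relabels leaves to species names and keeps provenance
batch = disco([family], mapping, min_size=2)
print(f"batch: {batch.n_input_trees} family -> {len(batch.trees)} single-copy trees,"
      f" {batch.discarded_leaves} leaves dropped by the size filter")
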