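"""Measure rooting error between two rooted trees with the normalized
clade distance (nCD).

nCD is the rooted analogue of Robinson-Foulds: the symmetric difference of
the two trees' clade sets divided by 2n-4, its maximum. When both trees
share the same unrooted topology it equals twice the number of edges
between the two root positions, divided by 2n-4.
"""

from multiroot import ncd, parse_newick

r_true = parse_newick("((((a,b),c),d),e);")
r_est = parse_newick("(((a,b),c),(d,e));")  # same topology, root one edge off

report = ncd(r_true, r_est)
print(f"clade symmetric difference: {report.clade_diff}")
print(f"root distance (edges):      {report.root_distance}")
print(f"nCD:                        {report.ncd:.3f}")
print()
print("A rooting one edge from the truth on 5 taxa scores nCD = 2/6 = 0.333;")
print("identical rooted trees score 0, a maximally wrong root scores 1.")
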