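"""Build a disease network from seed genes by one-hop expansion.

A synthetic background interaction network stands in for a thresholded
STRING-style graph; three seed genes are mapped onto it and expanded with
their distance-1 neighbours, keeping the full induced subgraph.
"""

from netsuit import build_disease_network
from netsuit.synth import make_graph

background = make_graph("barabasi_albert", 100, m=3, seed=1, name="background")
seeds = ["G000", "G005", "G042", "NOT_A_GENE"]

net = build_disease_network(background, seeds, name="demo_disease")

n_seed = sum(1 for o in net.origins().values() if o == "seed")
n_exp = sum(1 for o in net.origins().values() if o == "expanded")
print(f"background: {background.number_of_nodes()} nodes, "
      f"{background.number_of_edges()} edges")
print(f"disease network: {net.number_of_nodes()} nodes "
      f"({n_seed} seed + {n_exp} expanded), {net.number_of_edges()} edges")
print(f"seeds not found in background: {net.unmapped_seeds}")

# The expanded nodes are exactly the neighbours of the seeds; every edge of
# the background between any two retained nodes is kept (induced subgraph),
# so the network's density reflects the background, not a seed-star shape.
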