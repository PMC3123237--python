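"""Inspect the vertex-weight table that orders cluster seeding.

The weight of a vertex is k_max * d: the largest degree in its inclusive
neighbourhood times that neighbourhood's edge density.  On a star, the
leaves outweigh the hub — each leaf's two-node neighbourhood is complete
(d = 1) and contains the hub (k_max = 3), while the hub's own neighbourhood
is sparse.
"""

import networkx as nx

from minenet import compute_vertex_weights

star = nx.Graph([("hub", "leaf1"), ("hub", "leaf2"), ("hub", "leaf3")])
weights = compute_vertex_weights(star)
print(weights.to_frame().to_string(index=False))
# Densely grouped vertices attached to hubs score highest, so cluster
# growth starts inside candidate modules rather than at the hubs that
# connect many modules.
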