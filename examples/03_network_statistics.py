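"""Contrast the two topological regimes the generators emulate.

Sparse, strongly modular networks have long characteristic path lengths and
clean module boundaries; dense, interconnected networks have short paths and
blurred boundaries.  Sliding p_out toward p_in moves a planted-partition
graph between the regimes.
"""

from minenet import network_stats, planted_partition

for label, p_out in [("modular (low p_out)", 0.01), ("interconnected (high p_out)", 0.3)]:
    graph, _ = planted_partition(n_blocks=6, block_size=8, p_in=0.9, p_out=p_out, seed=5)
    stats = network_stats(graph)
    print(
        f"{label:<28} density={stats.density:.4f} "
        f"characteristic path length={stats.characteristic_path_length:.2f}"
    )
# Higher density and shorter paths mean modules are less separable from the
# rest of the network — the regime where modularity-aware admission matters.
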