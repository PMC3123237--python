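# minenet

Agglomerative detection of overlapping, high-modularity modules in
molecular interaction networks.

Groups of physically interacting gene products — complexes and functional
modules — show up in interaction networks as densely interconnected regions.
Finding them is easy in sparse, strongly modular interactomes (like
high-confidence yeast maps) and hard in dense, highly interconnected ones
(like the *C. elegans* protein–protein interaction network), where module
boundaries blur and greedy seed-expansion methods absorb spurious
neighbours. `minenet` implements a seed-expansion clustering algorithm built
for the dense regime: it weights vertices by their local neighbourhood, and
checks a *local modularity* score at every growth step so that cluster
boundaries track the network's real separation structure. Clusters are
non-exclusive — a protein may belong to several modules — and highly
overlapping clusters are merged rather than reported as parent/child
duplicates.

Intended users: computational biologists clustering protein–protein or
genetic interaction maps, and anyone benchmarking overlapping community
detection on graphs with planted ground truth.

## The algorithm

The network is an undirected, unweighted graph *G* = (*V*, *E*).

**Vertex weighting.** For each vertex *v* with inclusive depth-1
neighbourhood *N*∪*v*, the weight is

    v_w = k_max · d,     d = 2 e_{N∪v} / (V_{N∪v} (V_{N∪v} − 1))

where *d* is the neighbourhood's edge density and *k_max* the largest
(whole-graph) degree of any of its members. Dense groups attached to hubs
score highest and are inspected first as seeds.

**Cluster growth.** From each seed (all vertices, in descending weight
order) a cluster *C* grows breadth-first. A candidate neighbour *n*,
enqueued by member *v_s*, is admitted iff either

- **A)** `v_w(n) ≥ v_w(v_s)·(1 − vwp)` and admitting *n* does not decrease
  the local modularity `C_mod = E_in / E_out` by a relative margin of
  `msp`, or
- **B)** admitting *n* improves `C_mod` by more than that margin, even if
  the weight test fails.

Grown clusters are *culled* (members whose removal improves `C_mod` by more
than the `msp` margin are dropped, to a fixed point), optionally *trimmed*
(members with < 2 intra-cluster edges removed), merged into any earlier
cluster they overlap by ≥ `mp` of the smaller (default 50%), and scored

    C_s = d · V_C        (cluster density × size).

Clusters of size 1–2 are discarded.

**Evaluation.** Predicted clusters are matched to annotated complexes/GO
terms by a one-sided hypergeometric test (universe = network nodes,
significant at p ≤ 0.05); recall `TP/(TP+FN)`, precision `TP/(TP+FP)` and
geometric accuracy `√(R·P)` are averaged over matched complexes. A
composite modularity `Q = Σ_c [E_cIn/E_total − ((2E_cIn + E_cOut)/(2E_total))²]`
summarizes how well all clusters separate from the network.

## Worked example

`examples/01_planted_ring_recovery.py` builds a ring of five 6-cliques
joined by single bridge edges, clusters it, and evaluates against the
planted truth:

```
network: 30 nodes, 80 edges
found 5 clusters:
  #1: size=6 density=1.00 E_in=15 E_out=2 local_modularity=7.50
  ...
vs ground truth: mean recall=1.000 precision=1.000 geometric accuracy=1.000
```

Each planted clique has 15 internal edges and exactly two bridges, so a
perfectly recovered module shows density 1.0 and local modularity
15/2 = 7.5; geometric accuracy 1.0 means every clique was recovered exactly.
The other examples cover annotation matching (`02`), the sparse-vs-dense
topological regimes (`03`) and the vertex-weight table (`04`).

The same pipeline is available from the shell:

```sh
mine synth ring --n-cliques 5 --clique-size 6 --seed 7 --out ring.tsv --truth truth.gmt
mine cluster --network ring.tsv --vwp 1.0 --msp 0.0 --no-trim --out clusters.tsv
mine evaluate --clusters clusters.tsv --network ring.tsv --annotations truth.gmt --out report.tsv
```

`mine cluster` defaults (vwp = 0.9, msp = 0.3, trim on) are the operating
point found best for a dense metazoan interactome; `mine --help` documents
every flag.

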