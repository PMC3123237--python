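# Methods

## Model and procedure

`minenet` treats an interactome as a simple undirected, unweighted graph of
string-identified gene products. Module detection is agglomerative and
runs in five stages; all of them operate on two integers per candidate
cluster — `E_in` (edges inside the member set) and `E_out` (edges crossing
its boundary) — and the local modularity `C_mod = E_in / E_out`.

1. **Weighting.** Each vertex gets `v_w = k_max · d` over its inclusive
   depth-1 neighbourhood: `d` is the neighbourhood edge density
   `2e/(n(n−1))` and `k_max` the largest degree of any neighbourhood member,
   measured in the whole graph. The whole-graph reading of `k_max` ("the
   maximal number of edges connected to any single node") is a deliberate
   choice; an induced-subgraph reading would systematically discount
   neighbourhoods adjacent to hubs, which is exactly the signal the product
   is meant to capture. Weights are computed once and never updated.
2. **Growth.** Every vertex seeds a cluster, in descending weight order.
   Growth is breadth-first with a FIFO queue; each queue entry remembers the
   member that enqueued it (`v_s`). A popped candidate `n` is admitted iff
   (A) `v_w(n) ≥ v_w(v_s)(1 − vwp)` and `mod(C∪n) > mod(C) − mod(C)·msp`,
   or (B) `mod(C∪n) > mod(C) + mod(C)·msp`. Admitted nodes enqueue their
   not-yet-seen neighbours; rejected nodes are not reconsidered for that
   seed.
3. **Culling.** Any member whose removal satisfies
   `mod(C∖v) > mod(C) + mod(C)·msp` is removed; the scan restarts after
   each removal and stops at a fixed point.
4. **Trim** (optional, on by default). One simultaneous pass removes every
   member with fewer than two intra-cluster edges, judged against the
   pre-pass membership. Degree is measured inside the cluster-induced
   subgraph; whole-graph degree would almost never fire on hub-rich
   networks.
5. **Merge and filter.** The finished cluster merges into the first earlier
   cluster (creation order) it overlaps by at least `mp` of the *smaller*
   of the two; merging is a set union with statistics recomputed, without
   re-growth, and earlier clusters are not rescanned retroactively.
   Clusters with fewer than `min_size` members are dropped at the end, and
   output is ranked by score `C_s = density · size` (ties: larger first,
   then lexicographically smallest member).

## Parameters

| name | default | range | meaning |
|------|---------|-------|---------|
| `vwp` | 0.9 | [0, 1] | weight tolerance: candidate passes at `v_w ≥ v_w(v_s)(1−vwp)`. 1.0 disables the weight test; 0.0 demands candidates match their source's weight. |
| `msp` | 0.3 | [0, 1] | relative modularity margin for admission (A and B) and culling. 0 makes admission require a strict modularity increase. |
| `mp` | 0.5 | (0, 1] | merge threshold on `|A∩B| / min(|A|,|B|)`. |
| `trim` | on | — | haircut pass (stage 4). |
| `min_size` | 3 | ≥ 1 | smallest reported cluster; size-1/2 groups are not meaningful modules. |
| `alpha` | 0.05 | (0, 1] | significance cutoff for the hypergeometric cluster↔complex match. |
| set sizes | 3–100 | — | annotation sets outside this range are too specific/general and are excluded at read time. |

The clustering defaults are the operating point that balances modularity
and accuracy on a dense metazoan interactome; all are exposed as library
arguments and CLI flags.

## Numerical conventions

- **Degenerate modularity.** `E_in = 0` gives `C_mod = 0` (covers
  singletons and independent sets); `E_out = 0` with `E_in > 0` gives a
  `+inf` sentinel that orders above every finite score. From `+inf`,
  criterion B can never fire, and criterion A accepts only a candidate that
  keeps the score at `+inf` (never at `msp = 0`, where strict comparison
  rejects "no change"). During growth the `+inf` branch is actually
  unreachable — a candidate neighbour implies `E_out ≥ 1` — so its only
  effect is that no member of an isolated whole-component cluster is ever
  culled.
- **Strict comparisons.** All modularity comparisons use strict `>`, and the
  thresholds are computed exactly as written (`old − old·msp`,
  `old + old·msp`).
- **Determinism.** Seed order, queue insertion among a node's neighbours,
  and the cull scan are all fully ordered (descending weight then
  lexicographic for the first two, lexicographic for the cull). The queue
  ordering matters: enqueueing a member's neighbours in weight order means
  a growing cluster consolidates its dense core before judging boundary
  candidates, which is what lets a bridge-adjacent seed recover its own
  clique instead of leaking across the bridge. Identical inputs and
  parameters produce identical output, independent of graph construction
  order.
- **Duplicate queue entries.** A node can be enqueued by several members
  before it is first processed; it is marked visited when popped (admitted
  or rejected) and silently skipped on later pops.
- **Hypergeometric universe.** The test's population is the node set of the
  input network, and each annotated set is restricted to network members
  before computing TP/FN — the standard enrichment convention. Sets with no
  member in the network are excluded and logged. Tie-breaks for "most
  significant cluster" are: smaller p, larger overlap, smaller cluster,
  lower cluster index.
- **Aggregation.** Mean recall/precision/geometric accuracy are taken over
  complexes with a significant match; `include_unmatched=True` (CLI
  `--count-unmatched`) instead counts unmatched complexes as zeros for
  sensitivity analysis. Empty means are NaN.
- **Composite modularity.** The aggregate score uses the Newman–Girvan
  community form `Q = Σ_c [E_cIn/E_total − ((2E_cIn + E_cOut)/(2E_total))²]`,
  chosen because it is built from exactly the three edge counts the local
  score already uses; it is isolated in one function (`global_modularity`)
  so an alternative composite can be swapped in. Only clusters fully inside
  the largest connected component enter the sum. A single cluster covering
  a connected graph gives Q = 0 identically.
- **Characteristic path length** averages shortest paths over connected
  node pairs only, so multi-component networks still report a finite value;
  it is NaN when no connected pair exists.
- **Pipeline order.** Culling precedes trimming. The two orders disagree
  only on clusters that are both modularity-prunable and haircut-prunable;
  putting the modularity criterion first keeps the trim a purely cosmetic
  final step, and on the benchmark fixtures in this repository the two
  orders coincide.

## Synthetic benchmarks

Two seeded generators (numpy PCG64; fixed so fixtures are reproducible
across releases) provide ground-truthed inputs spanning the two topological
regimes seen in real interactomes:

- `ring_of_cliques(n_cliques, clique_size, n_noise_edges, seed)` — complete
  cliques joined in a ring by single bridge edges (clique *i*'s last member
  to clique *i+1*'s first, so every clique has exactly two boundary edges
  and closed-form local modularity `E_in/2`), plus uniformly drawn noise
  edges. This is the sparse/modular regime and the canonical
  planted-recovery fixture: at `vwp=1.0, msp=0` the algorithm recovers each
  clique exactly.
- `planted_partition(n_blocks, block_size, p_in, p_out, seed)` — equal
  blocks with independent within-block probability `p_in` and between-block
  probability `p_out`. Raising `p_out` toward `p_in` raises density and
  shortens the characteristic path length, moving the graph from the
  modular to the dense interconnected regime.

What these emulate — and what they do not: planted graphs have homogeneous
block sizes, near-uniform degrees and uniform background noise. Real
interactomes have heavy-tailed degree distributions, complexes of widely
varying size and cohesion, and study-bias artefacts; passing the planted
benchmarks demonstrates algorithmic correctness (formula fidelity, exact
recovery where recovery is information-theoretically easy, sane parameter
response), not biological performance on a particular organism's network.
One concrete consequence: on a uniform planted-partition graph the
permissive default setting (`vwp=0.9, msp=0.3`) lets growth cascade across
blocks through background edges until a single giant cluster remains —
criterion A tolerates 30% modularity drops, and the uniform noise provides
a connecting path at every boundary. On such graphs the strict regime
(`vwp=1.0, msp=0`) is the appropriate recovery setting; heterogeneous real
networks, where boundary drops are far larger, are what the permissive
default is for.

## Problem sizes

The test suite and `scripts/acceptance.py` use: exhaustive/random oracle
checks on graphs of ≤ 12 nodes (hundreds of graphs); step-by-step
interpreter equivalence on > 500 random graphs of ≤ 8 nodes across a
parameter grid; planted recovery on the 30-node ring fixture and a 48-node
planted partition; and one interactome-scale run on a 3000-node,
~15,000-edge planted partition (about a minute on one CPU). These sizes
were chosen so the full pipeline, including the naive reference
interpreter, runs comfortably on a laptop while still exercising every
code path at realistic scale.

## Known limitations

- The merge step is first-hit and non-retroactive: a merged union can in
  principle overlap a later-created cluster by more than `mp`. Raising `mp`
  usually increases the number of reported clusters but this is not
  guaranteed in adversarial cases, since merging changes the clusters that
  later candidates are compared against.
- Culling is a fixed-point loop and can, at extreme parameter values,
  dismantle most of a grown cluster; the subsequent size filter hides this
  for sizes < `min_size`.
- Edge weights, background-distribution weight thresholds, inter-cluster
  linker detection and condition-specific sub-network clustering are out of
  scope.
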