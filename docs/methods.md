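# Methods

## Model and procedure

The package treats a region's human mobility as a weighted co-occurrence
network over a fixed set of locations: vertices are locations, and the
weight of edge *(u, v)* counts the distinct users who produced at least
one geotagged event at both *u* and *v*. No trajectory order or timing
enters the graph — co-presence of a user at two places is the unit of
evidence, so the network is undirected and repeat visits do not inflate
weights. Events are first snapped to the nearest location by great-circle
distance (spherical radius 6371.0088 km; at city-to-country extents the
ellipsoidal correction is orders of magnitude below the resolution of
percentile ranks). Locations visited by fewer users than the degree
threshold are removed once, as their edges are dominated by sampling
noise.

Scale enters through the edge-distance distribution. Sorting edge
distances and cutting at the *s*-th nearest-rank percentile threshold
*mₛ* yields a nested family of graphs *G₁ ⊆ … ⊆ G₁₀₀ = G*. Percentiles,
not absolute distances, make scales comparable across regions whose
extents differ by orders of magnitude; the absolute radii corresponding
to each percentile are region-specific outputs, not inputs.

Each *Gₛ* is partitioned by a Louvain-class modularity heuristic. The
heuristic is stochastic and approximate, so each graph is partitioned
`n_partition_runs` times with run-indexed seeds and the run with the
highest weighted Newman–Girvan modularity is kept (ties to the earliest
run). Partitions are then smoothed on the Voronoi tessellation of the
locations: in synchronous sweeps, a cell adopts a competing value exactly
when that value holds a *strict* majority (> 1/2) of the cell's closed
neighbourhood. Smoothing removes salt-and-pepper noise from the purely
topological community detection without inventing labels.

Scale similarity is the Rand index δ: the fraction of unordered location
pairs classified concordantly (together/apart) by two partitions,
computed exactly through the contingency-table identity. The resulting
100×100 similarity matrix typically shows sharp block structure; the
blocks are found by maximising the interval separation

σ(B) = ( Σⱼ |Iⱼ| · mean within-interval δ ) / ( Σⱼ |Iⱼ| ) ÷ maxᵦ δ(P_{b−1}, P_b),

greedily adding breakpoints while σ strictly improves. Each interval — a
natural scale — is summarised by its prototypical percentile (largest
within-interval δ row sum) and by the absolute distance range
(m_{lo−1}, m_{hi}]. For joint visualisation, the per-scale labels of each
cell form a tuple and the same strict-majority rule is applied to whole
tuples (multi-scale smoothing), trading a little per-scale precision for
aligned boundaries across scales.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `n_percentiles` | 100 | resolution of the scale spectrum; percent scale |
| `min_vertex_degree` | 5 | drop locations seen by very few users (noise) |
| `n_partition_runs` | 100 | best-of-N protocol for the stochastic heuristic |
| `min_interval_size` | 5 | percentiles; stops noisy outliers becoming scales |
| `weighted_percentiles` | off | percentiles of distinct edges (default) or of movements (edges replicated by weight); both views are defensible, the distinct-edge one matches the formal Gₛ definition |
| `smoothing_max_sweeps` | 100 | hard stop for the majority iteration |
| `random_seed` | 0 | root of all run-level seeds |

Run seeds derive as `SeedSequence([root, percentile, run])`, so any stage
can be recomputed in isolation and whole runs are byte-reproducible.

## Numerical and procedural choices

- **Percentiles** are nearest-rank (the ⌈s·N/100⌉-th order statistic):
  deterministic, interpolation-free, and guaranteeing m₁₀₀ = max.
- **Majority** means strictly more than half of the closed neighbourhood
  held by a *single* competing value; a plurality never flips a cell, so
  smoothing cannot introduce labels and fixed points are well defined.
  Updates are synchronous (order-independent); a 2-cycle guard returns
  the first repeated state should the rule oscillate.
- **Adjacency** requires a shared Voronoi edge of positive length;
  point-contact cells (e.g. diagonal neighbours on a square lattice) are
  not neighbours. Topology is computed directly in lon-lat: only
  adjacency matters to smoothing, and it is invariant to the mild
  anisotropy of unprojected coordinates at regional extents.
- **σ bookkeeping**: breakpoints are interior points of (1, 100];
  within-interval similarity uses all unordered pairs of the interval;
  singleton intervals contribute similarity 1 with their size as weight;
  the denominator uses only the consecutive pair straddling each
  breakpoint. σ is undefined for an empty breakpoint set, so the search
  always places at least one breakpoint — consistent with every analysed
  region exhibiting at least two scales.
- **Ties** (breakpoint position, prototypical percentile, best-run
  selection, nearest-location assignment) always break toward the
  smaller percentile / earlier run / lexicographically smaller id:
  deterministic and data-independent.
- **Distance ranges** of natural scales are half-open (lower, upper],
  with the first scale closed below at 0, so every movement distance
  maps to exactly one scale when attributing users to scales.
- **Degenerate inputs**: an edgeless pruned graph, < 3 or collinear
  seeds, domains of < 2 locations, and partitions not covering the
  domain all raise errors; an all-identical scale space yields a
  degenerate (all-zero) normalised dissimilarity with a warning.
- The Louvain heuristic itself and the modularity functional are consumed
  from networkx behind the module surface; the bespoke logic is the
  multi-run protocol, the tie-breaking, and the exhaustive merge of k
  communities into the best two groups (all 2^{k−1} − 1 splits, guarded
  at k ≤ 25).

## The synthetic generator

Real geosocial feeds are unavailable for redistribution, so the package
ships a generator that emulates their structure with planted ground
truth. The world has two levels: regions on a 300 km lattice, three towns
per region placed at exactly equal angles on a 30 km ring (so all
same-region town pairs share one characteristic distance), and locations
uniform in 3 km town discs. Consecutive level spacings are kept ≥ 5×
apart — checked at construction and verifiable from the generated
coordinates — so movement distances fall into three disjoint bands
(≲ 6 km, ≈ 46–58 km, ≳ 230 km). Users get a home town (round-robin, so
towns are evenly populated) and draw each movement by first sampling a
regime — intra-town 0.7, intra-region 0.25, inter-region 0.05 — then a
uniform location in that stratum. The default acceptance fixture is
2 regions × 3 towns × 15 locations with 500 users × 10 movements;
pipeline tests run it at `n_partition_runs = 20`, which keeps a full
100-percentile run around twenty seconds on one CPU while leaving the
best-of-N protocol intact.

On this fixture the pipeline's expected output is two natural scales: a
short-range one whose partitions are the towns and a long-range one whose
partitions are the regions, with the transition percentile set by where
accumulated inter-town edge weight makes merging towns
modularity-favourable. Because the merge is driven by finite samples of
user co-occurrence, a narrow transition zone of intermediate partitions
survives on some seeds; when that zone is at least `min_interval_size`
wide and internally coherent the breakpoint search legitimately reports
it as a third scale. Across seed batteries this occurs in roughly one run
in ten.

What the generator does *not* emulate: heavy-tailed user activity,
temporal dynamics, spatially heterogeneous location density, fuzzy or
overlapping community structure, and observation noise beyond a small
positional jitter (50 m) on events. Passing the planted-recovery tests
therefore shows the machinery is correct and sensitive to genuinely
multi-scale structure; it does not show that real regions have two
scales, nor calibrate absolute thresholds for any real region.

## Known limitations

- The Voronoi construction is planar in lon-lat; for regions spanning
  tens of degrees of latitude, cell shapes (not adjacency) become
  distorted, and boundary geometry is exported unprojected.
- Breakpoint search is greedy; it matches exhaustive search on clean
  block structure but carries no optimality guarantee on adversarial
  similarity matrices.
- The exhaustive bipartition enumerates merges of detected communities,
  not vertex-level bipartitions; this mirrors the validation procedure
  it implements, not a general min-cut.
- Percentile thresholds tie all scale semantics to the observed edge
  set; regions with very few edges produce coarse, repetitive
  thresholds.
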