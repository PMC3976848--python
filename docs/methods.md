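# Methods

## Model and assumptions

`overcover` detects overlapping communities — covers, not partitions — on
undirected, simple, unweighted graphs held in memory. The method rests on
three empirical observations about networks with evident modular structure:

1. the fraction of overlap nodes is small (typically under 10 %), so most
   nodes need to be examined exactly once;
2. whole-graph edge density is low (roughly 0.10–0.30), so a community
   quality score must weigh internal density, not just the boundary;
3. communities are built from triangles: a node set in which no triangle
   exists (a chain, a ring) is not a seedable community core.

### Community quality

A community `C` is summarized by `(n_C, k_in, k_out)`: member count,
internal edge count, and boundary edge count. Its weighted modularity is

    Q_C = β · 2·k_in/(n_C(n_C−1)) + (1−β) · 2·k_in/(2·k_in + k_out),

a convex blend of internal density and cohesion. `Q_C = 1` exactly for an
isolated clique. The cohesion term alone is the classical local fitness
`2·k_in/(2·k_in + k_out)^α`; fitness assigns 1.0 to *any* isolated
subgraph, which is why it cannot distinguish a clique from a ring, while
the blend can (1.0 vs 0.9 at n=5, β=0.2). Cover-level modularity is the
unweighted mean over communities — communities are judged individually,
not traded off against one another.

### Membership

The belonging factor `a_iC` of node `i` in community `C` is the fraction
of `i`'s neighbors that are members of `C`. A neighbor shared by several
communities counts toward each of them, so the factors of an overlap node
sum to ≥ 1.0 (edges into an overlap region are internal to every community
that region touches). A membership vector `[a_1 … a_c]` is *averagely
distributed* when `Σ|a_r − 1/c| ≤ 1/(2c)`; the threshold tightens as the
membership number `c` grows. Boundary cases are inclusive — `[0.3, 0.4,
0.4]` deviates by exactly 1/6 and passes.

### Bridgeness

Original bridgeness `1 − sqrt(c/(c−1)·Σ(a_r − 1/c)²)` is 0 for a
single-community node and 1.0 for an exactly even split, regardless of how
connected the node is. The improved score

    b_i = 1 − sqrt( c/(c−1)·Σ(a_r − ā_i)² + 1/c² + 1/k_i )

centres the spread on the node's actual mean factor `ā_i` (the factors of
an overlap node sum past 1, so `1/c` is not their mean) and adds penalty
terms that shrink with membership number and degree; it is strictly
increasing in degree at fixed factors and always below 1 for finite
degree. It requires `c ≤ k` (a node cannot belong to more communities than
it has neighbors).

## The two-stage algorithm

**Stage 1a — raw detection.** Pick an unvisited root (uniformly under the
run's seed, or from a user-supplied root sequence). Its *core* is the root
plus every unlocated neighbor closing a triangle with the root inside the
candidate set; a core of fewer than 3 nodes is abandoned (the root stays
visited). Expansion is layer-wise: the frontier is every unlocated
non-member neighbor of the previously joined layer, examined in
lexicographic order; each frontier node is marked visited and joins if it
passes, in priority order: (1) ΔQ > 0; (2) density rises and |ΔQ| ≤
`stability_eps`; (3) links into the community exceed `n_C/3` (strict);
(4) Q after joining clears `q_threshold` with |ΔQ| ≤ `stability_eps`.
Expansion ends when a layer admits nobody or `max_layers` is hit.
Communities smaller than `min_output_size` at finalization are dissolved
back to the unallocated pool (members stay visited). Community counts are
maintained incrementally (O(degree) per candidate), never recounted.

**Stage 1b — locate.** When a community is output, each member whose best
belonging factor reaches `locate_belonging` (3/4) *and* whose incident
edges touch overlap nodes at a rate below `locate_overlap_edge_ratio`
(1/4) is marked located and pruned from every later frontier and from
correction. The pair is deliberately strict so that every plausible
overlap candidate survives to stage 2. Flags are raised, never cleared.

**Stage 1c — redistribution.** Visited-but-unallocated nodes are processed
as connected components, largest first. Triangle-connected groups inside a
component are too interdependent for any single member to pass a join
test: a group of at least `min_output_size` nodes is re-detected as one or
more independent communities (raw detection on the induced subgraph, so a
group spanning two dense regions bridged by a noise edge splits); smaller
groups join a neighboring community as one block. Remaining nodes touching
the cover join the best-ranked adjacent community (ranked by links, then
resulting Q; first one passing conditions 1–3 wins, otherwise the
top-ranked candidate is force-joined so the cover stays total). Nodes that
reach the cover only through other unallocated nodes are the tail of a
chain and are marked isolated.

**Stage 2 — error detection and correction.** The *specific* nodes are
those still unlocated (lexicographic order). For each: list the adjacent
communities (holding a neighbor but not the node); join each one the node
passes conditions 1–3 for — this is where overlap nodes are born; if at
least two adjacent communities remain and the belonging factors over the
adjacent communities are averagely distributed, join them all (equal
split); then, if the node holds several memberships, re-check each — a
membership with factor below `correction_keep_factor` is dropped when
removal raises that community's Q. Because corrected overlaps change their
neighbors' factors, the procedure repeats on mutually linked overlap nodes
until a pass changes nothing (cycle detection plus a |V|-pass bound guard
convergence; both report `stable=False` rather than looping).

**Audit mode.** The same per-node procedure run over *all* nodes of an
externally supplied total cover; the cover is steady exactly when no
membership changes. The pipeline's own output is a fixed point of the
audit on every fixture tested.

## Parameters

| name | default | meaning |
|---|---|---|
| `beta` | 0.2 | density weight in Q, in (0, 0.5]; 20/80 Pareto split |
| `alpha` | 1.0 | fitness size regulator (fitness only) |
| `q_threshold` | 0.750 | quality floor for join condition 4; the observed minimum community Q at β=0.2 on networks with known structure |
| `stability_eps` | 0.015 | \|ΔQ\| bound meaning "stable" |
| `link_frac` | 1/3 | join condition 3: links > `link_frac`·n_C |
| `locate_belonging` | 3/4 | belonging-factor bound of the locate rule |
| `locate_overlap_edge_ratio` | 1/4 | overlap-edge rate bound of the locate rule |
| `correction_keep_factor` | 1/3 | factor at which a membership is kept outright during correction |
| `min_core_size` | 3 | smallest triangle core that seeds a community |
| `min_output_size` | 5 | communities below this size are dissolved |
| `max_layers` | 6 | expansion depth bound (small-world diameter argument; logged when it binds) |
| `seed` | None | root-selection RNG; the only randomness in detection |

All thresholds are fractions of the quantities they bound; none carries
units. `correction_keep_factor` intentionally equals `link_frac`: a node
retains any membership it would still qualify to join. Setting it to
`locate_belonging` instead makes the removal step fire on nearly every
overlap membership (their factors hover near 1/2) and evicts genuine
overlaps.

## Numerical choices

- All node and frontier iteration is lexicographic on the string node ids;
  the only randomness is root choice under one seeded RNG, so a run is a
  pure function of (graph, parameters, seed, roots).
- Join condition 3 and the average-distribution bound differ deliberately
  in strictness: "more than" `n_C/3` is strict, `≤ 1/(2c)` is inclusive
  (a 1e-12 epsilon absorbs float noise at exact boundaries such as 1/6).
- Comparisons against printed reference tables use half-up rounding at the
  table's precision (3 dp for modularity, 2 dp for bridgeness).
- Degenerate inputs: quality functions reject `n_C < 2` or edgeless
  communities; `improved_bridgeness` rejects `c > k`; removal that would
  leave a community below 2 members or 0 internal edges is treated as
  −∞ gain (never taken); a graph with no triangles yields no communities
  and every node isolated.

## The synthetic generator

`make_planted_overlap` draws a planted-partition graph with overlaps:
blocks of designated sizes, within-block edge probability `p_in`,
cross-block `p_out`, and designated overlap nodes wired into each assigned
block at `p_in`. Defaults — three blocks of 10, `p_in = 0.9`,
`p_out = 0.02`, two overlap nodes (≤ 10 % of nodes) — model a network with
evident structure and a small overlap fraction, the regime the method is
designed for. An overlap node drawing fewer than two edges into a block is
re-anchored so the planted truth is realizable. Under these defaults the
pipeline recovers the planted cover (including overlap memberships, by set
equality) in 10/10 seeds; recovery degrades toward ~5/10 at the much
noisier corner `p_in = 0.8`, `p_out = 0.05`, where single noise edges can
rival planted overlap wiring.

What the generator does *not* emulate: heavy-tailed degree distributions,
nested or hierarchical modules, weighted or directed interactions, and
overlap regions wider than single nodes. Passing planted-recovery tests
therefore demonstrates correctness of the mechanics on block-structured
graphs, not performance on degree-heterogeneous real networks.

## Known limitations

- Whole-cover quality is a plain mean over communities, so the objective
  does not penalize adding many small high-Q communities; the size gates
  (`min_core_size`, `min_output_size`) stand in for that.
- A node examined while its neighborhood is still unallocated can be
  misjudged; stage 2 exists precisely for this, but nodes located early are
  never revisited, so an early wrong *location* (not observed on any
  fixture) would be uncorrectable.
- Chains and rings have no triangles and are unseedable by design; their
  nodes end isolated unless they touch a real community.
- The visited-flag pruning means detection order matters: different seeds
  can yield different (all stable) covers on graphs with ambiguous
  boundaries. Fixing `roots` makes a run exactly reproducible.
- Dense networks (density ≳ 0.2) shift the internal-strengthening overlap
  criterion to its neighbor-fraction form; the 0.20 switch point is an
  empirical default, configurable in `membership.overlap_condition`.
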