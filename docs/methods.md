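# Methods

## Model and definitions

The package operates on simple undirected graphs with unit edge weights
(vertices = neurons, edges = synapses; weighted synapses are out of scope).
For a fixed integer threshold `k ≥ 1`:

* threshold function: `f_k(S) = { v ∈ V : |N(v) ∩ S| ≥ k }`. The formula is
  applied literally — a member of `S` with fewer than `k` active neighbors
  drops out; the alternative `S ∪ f_k(S)` retention semantics is
  deliberately not used.
* invariant: `f_k(S) = S`; persistent: `S ⊆ f_k(S)`; weak: `f_k^n(S) = ∅`
  for some `n ≥ 1`.
* closure `cl_k(S)`: the fixed point of the iteration, when one exists.
* k-core: a nonempty vertex set inducing minimum degree ≥ k. Maximality and
  connectedness are *not* part of the definition; the classical maximal
  object is recovered by `maximum_kcore`. The empty set is excluded so that
  "contains a k-core" always means a nonempty one, which is the convention
  the experiment counts rely on.
* minimal k-core: no proper subset induces a k-core. Every minimal k-core
  is connected and has at least k+1 vertices.
* k-assembly: `cl_k(M)` for a minimal k-core `M`.

### Iteration semantics

Non-persistent sets can cycle under `f_k` (e.g. a diagonal pair of a
4-cycle at k = 2 alternates with the other diagonal forever). `iterate`
detects revisits with a seen-set and reports status `fixed_point`, `empty`,
or `cycle`; `closure` raises `ClosureUndefinedError` carrying the trace
rather than guessing a value. A user-settable `max_steps` exists purely as
a safety valve and fails loudly.

### A one-way implication, not an equivalence

For nonempty persistent `S`, the image `f_k(S)` is a k-core, and every
k-core is itself persistent. The converse — "`f_k(S)` is a k-core implies
`S` is persistent" — is **false**: attach a vertex `a` to one vertex of a
triangle `{c, d, e}` and take `S = {a, c, d, e}` at k = 2; then
`f_k(S) = {c, d, e}` is a 2-core while `a ∉ f_k(S)`. The property tests
therefore assert the two true directions only.

Palm's general *tight set* notion is not implemented: its published
formulation is grammatically incomplete and ambiguous about which
complement must fail to be weak. The predicates `is_persistent` / `is_weak`
are exposed so users can apply their preferred reading; the k-assembly
pipeline itself needs only minimal k-cores and closures.

## Algorithms

### Maximum k-core (greedy peel)

Repeatedly delete a minimum-degree vertex while its degree is below k. The
survivor set is the unique maximum k-core — the union of all k-cores — and
is independent of tie-breaking (tested against randomized tie-breaks); ties
are broken on the smallest vertex id so the recorded removal order is
reproducible. The core may be disconnected.

### Backtracking enumeration of minimal k-cores

The search generalizes Bron–Kerbosch from cliques to k-cores. Each node of
the search tree holds a k-core configuration `kcore`, a `not` set of
vertices that may no longer be deleted on this branch, and candidates — the
vertices whose deletion still leaves a k-core.

* Root: the maximum k-core of the input (every minimal k-core lies inside
  it); an empty peel means an empty answer.
* Report: a node reports `kcore` iff **every** single-vertex deletion peels
  to the empty set. This single test is equivalent to minimality and
  subsumes both the "no candidates" and the not-set report conditions.
* Branch: candidates are visited in ascending induced degree (ties on
  smallest id). Deleting candidate `s` need not leave a k-core directly, so
  the child configuration is the *peeled* maximum k-core of
  `kcore \ {s}` — peeling preserves every k-core that avoids `s`, so no
  minimal core is lost. A child whose peel evicted a `not` member is pruned:
  any minimal core below it contains all of `not`, would survive that peel,
  and has therefore already been reported on an earlier branch. After a
  branch returns, `s` joins `not`.

Uniqueness and completeness follow by induction: for a node `(kcore, not)`,
the subtree reports exactly the minimal k-cores `M` with
`not ⊆ M ⊆ kcore`, each once — `M` is handled precisely at the first
visited candidate it omits. The suite verifies this against the exhaustive
oracle rather than assuming it (240 seeded `G(n, p)` instances with
n ∈ {8..12}, p ∈ {0.2, 0.5, 0.7}, k ∈ {1..4}, plus hand fixtures).

Implementation notes:

* Vertex sets are integer bitmasks; adjacency is a list of neighbor masks,
  so subset copies and intersections are single int operations.
* Child peels run as targeted cascades from the deleted vertex (only
  vertices whose neighborhood lost a member can fall below k) instead of
  full rescans.
* If the configuration induces a k-regular subgraph, it is minimal iff
  connected (deleting any vertex cascades through its whole component);
  this makes the k = 2 leaf test — induced cycles — essentially free.
* The recursion depth is bounded by the maximum k-core's size; the
  recursion limit is raised to that bound plus slack.
* Node expansions are counted in `EnumerationResult.stats` so candidate
  selection heuristics can be compared. Ascending- versus
  descending-degree ordering produced identical node counts on dense
  `G(20, 0.7)` instances, so the ascending (smallest-degree) rule is kept.

### Baselines

`subset_oracle` scans all `2^n` subsets (guarded at n ≤ 20) and keeps the
sets that are k-cores whose every single-vertex deletion peels to nothing.
`naive_enumerate` implements the earlier branching scheme — report if the
current configuration is a minimal k-core, else peel and branch on every
single-vertex deletion — with a visited-configuration cache; without the
cache the scheme revisits the same subproblem factorially often, with it
each of the ≤ 2^n configurations is expanded once. Both exist to
cross-validate the backtracking search, not for production use.

### Bron–Kerbosch maximal cliques

Included for the structural cross-check that every (k+1)-subset of a clique
is a minimal k-core. Standard `compsub`/`candidates`/`not` recursion; the
pivot is the vertex of `candidates ∪ not` with the fewest disconnections to
`candidates`, and only candidates not adjacent to the pivot are extended.
Validated against an exhaustive subset scan and networkx's enumerator.

### Directed extension

`directed_kcore_filter` follows the undirected-first procedure: enumerate
the minimal k-cores of the underlying undirected graph, then keep those in
which every vertex has ≥ k in-neighbors (or out-neighbors) inside the set.
A directed structure that is not a minimal k-core of the undirected
projection is invisible to this filter; the incompleteness is inherent to
the procedure and documented rather than patched.

## Random-graph generators and the simulation harness

* Bernoulli `G(n, p)`: each unordered pair is an edge independently with
  probability p, driven by a `numpy` generator; the edge-count distribution
  is verified against Binomial(C(n,2), p) by a χ² test at α = 0.01.
* Random d-regular: configuration/pairing model, rejecting any pairing with
  a self-loop or repeated edge and redrawing; accepted samples are uniform
  over simple d-regular graphs. Exact uniformity is incidental — what the
  experiments need is seedability and simplicity. Disconnected samples are
  kept (no connectivity filter is applied), and the per-replicate counts
  make them visible: a connected 5-regular graph has exactly one minimal
  5-core (itself), a disconnected one has one per component.

`run_experiment` spawns one independent substream per replicate from a
single `SeedSequence`, so a (config, seed) pair reproduces graphs, counts
and CSV bytes exactly. Aggregation uses the conditional-mean convention:
`graphs_with_core` counts replicates with ≥ 1 minimal k-core, and
`conditional_mean_count` averages over those replicates only; the same
convention is applied to both graph models. Per-replicate counts are
retained for variance estimation (`sd_count`, standard errors).

### Study conditions and what the tests show

The replication suite runs 100 replicates at n = 10 (and for the 5-regular
model at n = 30), and 30 replicates at n = 15 and n = 20, comparing
conditional means within 3 estimated standard errors or 25% relative error
(whichever is looser; 4 SE for the sparse n = 20 spot check at reduced
replication). The n = 10 density-ordering comparison (minimal 2-cores vs
3-cores at p = 0.7 differ by only ~6%) uses 200 replicates to sharpen a
qualitative inequality that is otherwise near the noise floor. The n = 25
table scale is not run routinely — the counts there reach 10^5 per graph —
but nothing in the implementation is size-limited beyond time.

Synthetic graphs are exactly the model the theory addresses, so these tests
validate the algorithms, not biological realism: Bernoulli and regular
graphs have neither the degree heterogeneity, clustering, nor directedness
of cortical networks, and passing counts say nothing about how minimal
k-cores behave on such data. The directed filter and edge-list I/O exist
precisely so real connectomes can be tried.

## Degenerate inputs and numerics

All quantities are integers or exact ratios; there is no floating-point
tolerance anywhere in the algorithms. Empty graphs, empty seed sets,
thresholds exceeding all degrees, and disconnected cores are exercised in
the unit tests. Edge-list parsing reports the offending line number;
self-loops are rejected everywhere. Isolated vertices are not representable
in the edge-list format (a known limitation; construct such graphs
programmatically instead).
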